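"""Derive a stromal hypoxia signature from synthetic secretome and
microdissected-tissue proteomics.

Simulates conditioned-media secretomes (2 subtypes x 2 oxygen conditions,
planted hypoxia-responsive proteins) and paired epithelium/stroma tumor
proteomes (planted stroma-exclusive subtype differences), then runs the
full derivation: per-subtype hypoxia t-tests -> hypoxome union; stroma
and epithelium subtype t-tests -> stroma-exclusive set; intersection ->
the signature.
"""

import hypoxsig as hx

m, design, truth_sec = hx.simulate_secretome(hx.SecretomeSimConfig(seed=0))
mt, design_t, truth_tis = hx.simulate_tissue(hx.TissueSimConfig(seed=0))

tab_lum = hx.differential_test(
    m, design, hx.Contrast("oxygen", ("normoxia", "hypoxia"),
                           {"subtype": "luminal"}))
tab_bas = hx.differential_test(
    m, design, hx.Contrast("oxygen", ("normoxia", "hypoxia"),
                           {"subtype": "basal"}))
set_lum, set_bas, hypoxome = hx.derive_hypoxome(tab_lum, tab_bas, alpha=0.05)

stroma_excl = hx.derive_stroma_exclusive(
    hx.differential_test(mt, design_t, hx.Contrast(
        "subtype", ("luminal", "basal"), {"compartment": "stroma"})),
    hx.differential_test(mt, design_t, hx.Contrast(
        "subtype", ("luminal", "basal"), {"compartment": "epithelium"})),
    alpha=0.05)

signature = hx.intersect_signature(hypoxome, stroma_excl)

expected = ((set(truth_sec.planted["hypoxia_luminal"])
             | set(truth_sec.planted["hypoxia_basal"]))
            & set(truth_tis.planted["stroma_exclusive"]))
hit = len(set(signature.members) & expected)

print(f"hypoxia-increased: {len(set_lum)} luminal, {len(set_bas)} basal, "
      f"union {len(hypoxome)}")
print(f"stroma-exclusive subtype differences: {len(stroma_excl)}")
print(f"derived signature: {len(signature)} proteins")
print(f"planted intersection recovered: {hit}/{len(expected)} "
      f"(precision {hit/len(signature):.2f}, recall {hit/len(expected):.2f})")
# The derived signature is the set of secreted hypoxia-response proteins
# that also mark stroma-specific subtype differences; precision/recall are
# measured against the generator's planted ground truth.
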