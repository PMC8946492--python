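"""Reference-vs-deletion-variant comparison: the full report bundle.

The variant deletes residue 508, doubles the noise of the α-helical
subdomain region, and weakens the planted interface contacts; the pipeline
should flag the destabilised region, the score shift, and the NBD1/TMD2
interface.
"""

import json

import structens as se

ref_spec = se.cftr_like_spec(seed=21, scale=0.3)
var_spec = se.make_variant_spec(
    ref_spec,
    deletion_position=508,
    destabilized_regions={"alpha_subdomain": 2.0},
    weaken_contacts=0.5,
)

reference = se.perturb_ensemble(se.make_scaffold(ref_spec), ref_spec, 400, tag_prefix="wt")
variant = se.perturb_ensemble(se.make_scaffold(var_spec), var_spec, 400, tag_prefix="mut")

report = se.run_comparison(
    reference_ensemble=reference,
    variant_ensembles={"f508del_like": (variant, var_spec.correspondence())},
    domain_map=ref_spec.domain_map(),
    out_dir="scratch/comparison_run",
    selection_fraction=0.1,
    seed=0,
)

v = report["variants"]["f508del_like"]
print(f"score shift (best 5% vs best 5%): p = {v['score_shift_p']:.2e} [{v['score_shift_label']}]")
print(f"largest flexibility increase at residue {v['delta_profile_argmax']} "
      f"(ΔRMSD {v['delta_profile_max']:.2f} Å) — inside the destabilised 500-540 region")
for iface, entry in report["interfaces"].items():
    r = entry["f508del_like"]
    print(f"interface {iface}: median sum {r['median']:.2f} vs "
          f"{entry['reference']['median']:.2f} (reference), p = {r['p']:.2e} [{r['label']}]")
print("Less negative interface sums in the variant mean weakened residue "
      "contacts across that interface; stars follow p < 0.05/0.01/0.001/0.0001.")
print("full bundle (TSVs, B-factor maps, manifest) under scratch/comparison_run/")
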