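"""Residue-pair energies of one model and their aggregation over interfaces."""

import structens as se
from structens.energetics import boxplot_stats, interface_sums

spec = se.two_domain_spec(seed=31, length=30, n_contacts=3, contact_energy=-0.8)
scaffold = se.make_scaffold(spec)
dm = spec.domain_map()

table = se.surrogate_pair_energies(scaffold)
print(f"{len(table)} contacting residue pairs (representative atoms within 8 Å)")
print(f"interface A/B sum on the scaffold: {se.interface_energy(table, dm, 'A', 'B'):.2f} "
      "(REU-like; includes the 3 planted contacts at -0.8 each)")

ensemble = se.perturb_ensemble(scaffold, spec, 80)
sums = interface_sums(ensemble, dm, "A", "B")
stats = boxplot_stats(sums)
print(f"ensemble interface sums: median {stats['median']:.2f}, "
      f"IQR [{stats['q1']:.2f}, {stats['q3']:.2f}] over {stats['n']} models")
print("Positional noise jitters each contact distance, spreading the per-model "
      "interface sums around the planted total.")
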