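"""Per-residue flexibility profile of an ensemble, with per-domain alignment.

The CFTR-like generator plants elevated positional noise in the SDR segment
(residues 526-547); the profile recovers it.
"""

from pathlib import Path

import numpy as np

import structens as se

Path("scratch").mkdir(exist_ok=True)

spec = se.cftr_like_spec(seed=11, scale=0.3)
scaffold = se.make_scaffold(spec)
ensemble = se.perturb_ensemble(scaffold, spec, n_models=200)

profile = se.per_residue_profile(ensemble, scaffold, spec.domain_map(), per_domain=True)

sdr = profile.loc[526:547, "rms_deviation"].mean()
nbd1_rest = profile.loc[440:650].drop(range(526, 548), errors="ignore")["rms_deviation"].mean()
print(f"profiled {len(profile)} residues over {len(ensemble)} models")
print(f"SDR (526-547) rms deviation:       {sdr:.2f} Å")
print(f"rest of NBD1 rms deviation:        {nbd1_rest:.2f} Å")
print(f"expected for sigma=0.4 Å baseline: {0.4 * np.sqrt(3):.2f} Å (σ·√3)")
print("The elevated SDR band reproduces the planted flexibility; the 95% CI "
      "columns (ci_low/ci_high) bound the mean deviation per residue.")

se.ensemble_mean_profile_map(profile, scaffold, 0.0, 4.0, "scratch/profile_map.pdb")
print("wrote scratch/profile_map.pdb (B-factors carry the profile, clipped to 0-4 Å)")
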