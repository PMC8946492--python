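"""Superposition and per-residue flexibility profiling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import structens as se
from structens.superpose import kabsch_superpose, whole_structure_rmsd
from conftest import build_model, oracle_superpose_rmsd, score_only_ensemble


def _make_ensemble(models, scores=None):
    from structens.ensemble import Ensemble

    tags = [m.model_tag for m in models]
    scores = scores if scores is not None else list(range(len(models)))
    return Ensemble(models=models, scores=pd.DataFrame({"total_score": scores, "model_tag": tags}))


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------


def test_identical_sets_give_identity_and_zero_rmsd(rng):
    pts = rng.normal(size=(8, 3))
    rot, trans, rmsd = kabsch_superpose(pts, pts)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(trans, 0.0, atol=1e-9)
    assert rmsd == pytest.approx(0.0, abs=1e-10)


def test_exact_rigid_motion_is_recovered(rng):
    pts = rng.normal(size=(10, 3)) * 5
    true_rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    fixed = pts @ true_rot.T + np.array([5.0, 0.0, 0.0])
    rot, trans, rmsd = kabsch_superpose(pts, fixed)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(rot, true_rot, atol=1e-9)
    np.testing.assert_allclose(pts @ rot.T + trans, fixed, atol=1e-9)
    assert np.linalg.det(rot) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("n_points", [4, 7, 12])
def test_kabsch_matches_quaternion_grid_oracle(seed, n_points):
    """The SVD solution agrees with an exhaustive rotation-grid minimiser."""
    rng = np.random.default_rng(seed)
    moving = rng.normal(size=(n_points, 3)) * 4
    fixed = (
        Rotation.random(random_state=rng.integers(2**31)).apply(moving)
        + rng.normal(scale=0.4, size=(n_points, 3))
        + rng.normal(scale=5, size=3)
    )
    _, _, rmsd = kabsch_superpose(moving, fixed)
    assert rmsd == pytest.approx(oracle_superpose_rmsd(moving, fixed), abs=1e-3)


def test_kabsch_agrees_with_biotite(rng):
    import biotite.structure as struc

    moving = rng.normal(size=(20, 3)) * 3
    fixed = moving + rng.normal(scale=0.5, size=(20, 3))
    _, _, rmsd = kabsch_superpose(moving, fixed)
    fitted, _ = struc.superimpose(fixed, moving)
    ref_rmsd = float(np.sqrt(np.mean(np.sum((fitted - fixed) ** 2, axis=1))))
    assert rmsd == pytest.approx(ref_rmsd, abs=1e-6)  # biotite works in float32


def test_degenerate_inputs_rejected(rng):
    with pytest.raises(ValueError, match="3 paired"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, rng.normal(size=(5, 3)))


# ---------------------------------------------------------------------------
# Whole-structure RMSD
# ---------------------------------------------------------------------------


def test_model_vs_itself_is_zero(rng):
    model = build_model(range(1, 9), rng.normal(size=(8, 3)) * 5)
    assert whole_structure_rmsd(model, model) == pytest.approx(0.0, abs=1e-9)


def test_toy_chain_rmsd_matches_oracle(rng):
    ca_a = rng.normal(size=(5, 3)) * 4
    ca_b = Rotation.random(random_state=7).apply(ca_a) + rng.normal(scale=0.8, size=(5, 3))
    a = build_model(range(1, 6), ca_a)
    b = build_model(range(1, 6), ca_b)
    assert whole_structure_rmsd(a, b) == pytest.approx(oracle_superpose_rmsd(ca_a, ca_b), abs=1e-3)


def test_disjoint_residue_sets_error(rng):
    a = build_model([1, 2, 3], rng.normal(size=(3, 3)))
    b = build_model([10, 11, 12], rng.normal(size=(3, 3)))
    with pytest.raises(ValueError, match="no shared"):
        whole_structure_rmsd(a, b)


# ---------------------------------------------------------------------------
# Flexibility profiles
# ---------------------------------------------------------------------------


def test_identical_copies_profile_is_zero():
    spec = se.two_domain_spec(seed=3, length=10)
    scaffold = se.make_scaffold(spec)
    models = []
    for i in range(10):
        m = se.StructureModel(atoms=scaffold.atoms.copy(), model_tag=f"c{i}")
        models.append(m)
    prof = se.per_residue_profile(_make_ensemble(models), scaffold, spec.domain_map())
    assert np.allclose(prof["mean_deviation"], 0.0, atol=1e-9)
    assert np.allclose(prof["rms_deviation"], 0.0, atol=1e-9)
    assert (prof["n_models"] == 10).all()


def _closed_form_check(n_models=500, sigma=0.3, length=100, seed=11):
    """rms → σ√3 and mean → σ·2√(2/π) for isotropic per-residue noise."""
    spec = se.GeneratorSpec(
        domains=(se.synthetic.DomainLayout("A", 1, length),),
        seed=seed,
        base_sigma=sigma,
    )
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, n_models)
    prof = se.per_residue_profile(ens, scaffold, per_domain=False)
    rms_ratio = prof["rms_deviation"].mean() / (sigma * np.sqrt(3))
    mean_ratio = prof["mean_deviation"].mean() / (sigma * 2 * np.sqrt(2 / np.pi))
    return rms_ratio, mean_ratio


def test_rms_deviation_recovers_sigma_sqrt3():
    rms_ratio, mean_ratio = _closed_form_check()
    assert rms_ratio == pytest.approx(1.0, rel=0.05)
    assert mean_ratio == pytest.approx(1.0, rel=0.05)


def test_elevated_sigma_region_shows_in_profile():
    """A hot segment with doubled σ stands out against its flanks."""
    spec = se.two_domain_spec(seed=5, length=40, hot=(11, 20), hot_multiplier=2.5)
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, 100)
    prof = se.per_residue_profile(ens, scaffold, spec.domain_map())
    hot = prof.loc[11:20, "rms_deviation"].mean()
    flank = prof.loc[list(range(1, 11)) + list(range(21, 41)), "rms_deviation"].mean()
    assert hot > 1.5 * flank


def test_profiles_invariant_under_rigid_motion_of_members():
    spec = se.two_domain_spec(seed=9, length=12)
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, 20)
    prof = se.per_residue_profile(ens, scaffold, spec.domain_map())

    rot = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
    moved = []
    for m in ens.models:
        arr = m.atoms.copy()
        arr.coord = m.atoms.coord @ rot.T + np.array([10.0, -4.0, 7.0])
        moved.append(se.StructureModel(atoms=arr, model_tag=m.model_tag))
    prof2 = se.per_residue_profile(
        _make_ensemble(moved, list(ens.scores["total_score"])), scaffold, spec.domain_map()
    )
    np.testing.assert_allclose(
        prof[["mean_deviation", "rms_deviation"]], prof2[["mean_deviation", "rms_deviation"]],
        atol=1e-6,
    )


def test_per_domain_alignment_removes_interdomain_shifts():
    """Rigid inter-domain motion inflates a global profile but not a
    per-domain one — the reason for per-domain pre-alignment."""
    spec = se.two_domain_spec(seed=21, length=25, base_sigma=0.2, domain_shift_sigma=2.0)
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, 60)
    per_dom = se.per_residue_profile(ens, scaffold, spec.domain_map(), per_domain=True)
    glob = se.per_residue_profile(ens, scaffold, per_domain=False)
    local_level = 0.2 * np.sqrt(3)
    assert per_dom["rms_deviation"].mean() < 1.2 * local_level
    assert glob["rms_deviation"].mean() > 2.0 * local_level


def test_ci_band_covers_true_mean_deviation():
    """The nominal 95% band on the mean deviation achieves ≥90% empirical
    coverage (truth taken from a large reference ensemble)."""
    spec = se.two_domain_spec(seed=31, length=10, base_sigma=0.5)
    scaffold = se.make_scaffold(spec)
    dm = spec.domain_map()
    big = se.perturb_ensemble(scaffold, spec, 2000, seed=999)
    truth = se.per_residue_profile(big, scaffold, dm)["mean_deviation"]

    hits = total = 0
    for rep in range(200):
        ens = se.perturb_ensemble(scaffold, spec, 30, seed=1000 + rep)
        prof = se.per_residue_profile(ens, scaffold, dm)
        hits += int(((prof["ci_low"] <= truth) & (truth <= prof["ci_high"])).sum())
        total += len(prof)
    assert hits / total >= 0.90


def test_profile_invariants_hold():
    spec = se.two_domain_spec(seed=41, length=15)
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, 25)
    prof = se.per_residue_profile(ens, scaffold, spec.domain_map(), ci_method="bootstrap", seed=1)
    assert (prof["mean_deviation"] >= 0).all()
    assert (prof["rms_deviation"] >= prof["mean_deviation"] - 1e-12).all()
    assert (prof["ci_low"] <= prof["mean_deviation"] + 1e-12).all()
    assert (prof["mean_deviation"] <= prof["ci_high"] + 1e-12).all()


# ---------------------------------------------------------------------------
# Difference profiles and maps
# ---------------------------------------------------------------------------


def test_delta_profile_zero_antisymmetric_and_toy():
    a = pd.Series({1: 2.0, 2: 1.0})
    b = pd.Series({1: 0.5, 2: 1.5})
    assert (se.delta_profile(a, a) == 0).all()
    pd.testing.assert_series_equal(se.delta_profile(a, b), -se.delta_profile(b, a))
    assert se.delta_profile(pd.Series({1: 2.0}), pd.Series({1: 0.5})).loc[1] == 1.5
    with pytest.raises(ValueError, match="no residues"):
        se.delta_profile(pd.Series({1: 1.0}), pd.Series({5: 1.0}))


def test_profile_map_clips_to_range(tmp_path, rng):
    model = build_model([1, 2, 3], rng.normal(size=(3, 3)) * 5)
    prof = pd.Series({1: 6.0, 2: -0.1, 3: 2.5})
    out = tmp_path / "map.pdb"
    se.ensemble_mean_profile_map(prof, model, 0.0, 4.0, str(out))
    back = se.read_pdb(out)
    by_res = {int(r): float(back.atoms.b_factor[back.atoms.res_id == r][0])
              for r in np.unique(back.atoms.res_id)}
    assert by_res == {1: 4.00, 2: 0.00, 3: 2.50}
    with pytest.raises(ValueError, match="lo < hi"):
        se.ensemble_mean_profile_map(prof, model, 4.0, 0.0, str(out))
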