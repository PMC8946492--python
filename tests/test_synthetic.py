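"""Synthetic scaffold/ensemble generator and its ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import structens as se
from structens.synthetic import Contact, DomainLayout, GeneratorSpec, HotRegion, contact_distance
from structens.energetics import pair_potential, surrogate_pair_energies


def _two_20():
    return GeneratorSpec(
        domains=(DomainLayout("A", 1, 20, (0, 0)), DomainLayout("B", 31, 20, (1, 0))),
        seed=7,
    )


def test_scaffold_counts():
    scaffold = se.make_scaffold(_two_20())
    assert len(scaffold.residue_numbers()) == 40
    assert len(scaffold) == 80  # CA + CB per residue


def test_scaffold_deterministic():
    a = se.make_scaffold(_two_20())
    b = se.make_scaffold(_two_20())
    np.testing.assert_array_equal(a.atoms.coord, b.atoms.coord)


def test_helix_geometry_ca_spacing():
    scaffold = se.make_scaffold(_two_20())
    res, ca = scaffold.ca_table()
    for lo, hi in ((1, 20), (31, 50)):
        block = ca[(res >= lo) & (res <= hi)]
        d = np.linalg.norm(np.diff(block, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)


def test_cb_offset_length():
    scaffold = se.make_scaffold(_two_20())
    a = scaffold.atoms
    ca = a.coord[a.atom_name == "CA"]
    cb = a.coord[a.atom_name == "CB"]
    np.testing.assert_allclose(np.linalg.norm(ca - cb, axis=1), 1.53, atol=1e-5)


def test_overlapping_domain_placement_rejected():
    spec = GeneratorSpec(
        domains=(DomainLayout("A", 1, 20, (0, 0)), DomainLayout("B", 31, 20, (0, 0))),
        seed=1,
    )
    with pytest.raises(ValueError, match="overlap"):
        se.make_scaffold(spec)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


def test_zero_sigma_models_equal_scaffold():
    spec = GeneratorSpec(domains=_two_20().domains, seed=3, base_sigma=0.0)
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, 10)
    for m in ens.models:
        np.testing.assert_array_equal(m.atoms.coord, scaffold.atoms.coord)
    # scores reduce to baseline + noise
    sm = spec.score_model
    resid = ens.scores["total_score"] - sm.baseline
    assert abs(resid.mean()) < sm.noise  # centred on baseline
    assert resid.std() < 3 * sm.noise


def test_same_seed_reproducible():
    spec = _two_20()
    scaffold = se.make_scaffold(spec)
    a = se.perturb_ensemble(scaffold, spec, 5)
    b = se.perturb_ensemble(scaffold, spec, 5)
    for ma, mb in zip(a.models, b.models):
        np.testing.assert_array_equal(ma.atoms.coord, mb.atoms.coord)
    pd.testing.assert_frame_equal(a.scores, b.scores)


def test_scores_encode_displacement():
    """With positive coupling, the best-scoring tail has smaller realised
    displacement than the ensemble at large."""
    spec = _two_20()
    scaffold = se.make_scaffold(spec)
    ens = se.perturb_ensemble(scaffold, spec, 200)
    disp = {
        m.model_tag: float(np.sum((m.atoms.coord - scaffold.atoms.coord) ** 2))
        for m in ens.models
    }
    best = se.select_best(ens, fraction=0.05)
    mean_best = np.mean([disp[t] for t in best.tags])
    assert mean_best < np.mean(list(disp.values()))


def test_ensemble_n_models_validation():
    spec = _two_20()
    scaffold = se.make_scaffold(spec)
    with pytest.raises(ValueError):
        se.perturb_ensemble(scaffold, spec, 1)


# ---------------------------------------------------------------------------
# Deletion variants
# ---------------------------------------------------------------------------


def test_deletion_renumbers_downstream():
    ref_spec = se.cftr_like_spec(seed=2, scale=0.2)
    var_spec = se.make_variant_spec(ref_spec, deletion_position=508)
    ref = se.make_scaffold(ref_spec)
    var = se.make_scaffold(var_spec)
    assert len(var.residue_numbers()) == len(ref.residue_numbers()) - 1
    res_r, ca_r = ref.ca_table()
    res_v, ca_v = var.ca_table()
    # variant residue 508 carries the geometry of reference residue 509
    np.testing.assert_allclose(ca_v[res_v == 508][0], ca_r[res_r == 509][0])
    corr = var_spec.correspondence()
    assert corr.to_variant(508) is None
    assert corr.to_variant(509) == 508


def test_null_variant_profiles_indistinguishable():
    """multiplier 1.0 and no weakening: reference and variant ensembles give
    statistically indistinguishable profiles in ≥90% of replicates."""
    from structens.energetics import compare_interface_distributions

    spec = se.two_domain_spec(seed=61, length=15)
    scaffold = se.make_scaffold(spec)
    dm = spec.domain_map()
    ok = 0
    reps = 20
    for rep in range(reps):
        a = se.perturb_ensemble(scaffold, spec, 30, seed=200 + 2 * rep)
        b = se.perturb_ensemble(scaffold, spec, 30, seed=201 + 2 * rep)
        pa = se.per_residue_profile(a, scaffold, dm)["rms_deviation"]
        pb = se.per_residue_profile(b, scaffold, dm)["rms_deviation"]
        if compare_interface_distributions(pa.to_numpy(), pb.to_numpy()).p > 0.05:
            ok += 1
    assert ok / reps >= 0.90


def test_destabilized_region_shows_in_delta_profile():
    ref_spec = se.two_domain_spec(seed=71, length=40, hot=(11, 20), hot_multiplier=1.0)
    var_spec = se.make_variant_spec(ref_spec, destabilized_regions={"hot": 2.0})
    scaffold = se.make_scaffold(ref_spec)
    dm = ref_spec.domain_map()
    ref = se.perturb_ensemble(scaffold, ref_spec, 150)
    var = se.perturb_ensemble(scaffold, var_spec, 150)
    delta = se.delta_profile(
        se.per_residue_profile(var, scaffold, dm),
        se.per_residue_profile(ref, scaffold, dm),
    )["rms_deviation"]
    inside = delta.loc[11:20].mean()
    outside = delta.drop(range(11, 21)).mean()
    assert inside > 0.2
    assert inside > outside + 0.2


def test_make_variant_spec_validation():
    spec = se.two_domain_spec(seed=1, hot=(5, 10))
    with pytest.raises(KeyError, match="unknown"):
        se.make_variant_spec(spec, destabilized_regions={"nope": 2.0})
    with pytest.raises(ValueError):
        se.make_variant_spec(spec, weaken_contacts=0.0)
    spec_c = se.two_domain_spec(seed=1, n_contacts=1)
    anchor = spec_c.interface_contacts[0].res_i
    with pytest.raises(ValueError, match="anchors"):
        se.make_variant_spec(spec_c, deletion_position=anchor)


# ---------------------------------------------------------------------------
# Planted contacts
# ---------------------------------------------------------------------------


def test_planted_contact_energies_realised_exactly():
    spec = se.two_domain_spec(seed=81, n_contacts=3, contact_energy=-0.8)
    scaffold = se.make_scaffold(spec)
    table = surrogate_pair_energies(scaffold, spec.potential)
    got = {(int(r.res_i), int(r.res_j)): r.energy for r in table.itertuples()}
    for c in spec.interface_contacts:
        pair = (min(c.res_i, c.res_j), max(c.res_i, c.res_j))
        assert got[pair] == pytest.approx(c.energy, abs=1e-6)


def test_contact_distance_inverts_potential():
    for e in (-0.88, -0.5, -0.1, -0.01):
        d = contact_distance(e)
        assert pair_potential(d) == pytest.approx(e, abs=1e-9)
        assert 5.0 <= d < 8.0
    with pytest.raises(ValueError):
        contact_distance(0.5)


def test_weakened_contacts_raise_interface_energy():
    """Scaling contact energies toward zero makes the planted interface less
    favourable in the scaffold geometry."""
    from structens.energetics import interface_energy

    ref_spec = se.two_domain_spec(seed=91, n_contacts=3)
    var_spec = se.make_variant_spec(ref_spec, weaken_contacts=0.5)
    dm = ref_spec.domain_map()
    e_ref = interface_energy(surrogate_pair_energies(se.make_scaffold(ref_spec)), dm, "A", "B")
    e_var = interface_energy(surrogate_pair_energies(se.make_scaffold(var_spec)), dm, "A", "B")
    assert e_var > e_ref + 0.5  # three contacts weakened by 0.4 each


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def test_ground_truth_round_trip(tmp_path):
    spec = se.make_variant_spec(
        se.cftr_like_spec(seed=4, scale=0.2), deletion_position=508,
        destabilized_regions={"alpha_subdomain": 2.0}, weaken_contacts=0.5,
    )
    se.export_ground_truth(spec, tmp_path)
    assert se.load_ground_truth(tmp_path) == spec

    truth = pd.read_csv(tmp_path / "truth_sigma.tsv", sep="\t")
    ref_residues = set(int(r) for r in spec.reference_residues())
    assert set(truth["reference_residue"]) == ref_residues
    deleted = truth[truth["reference_residue"] == 508]
    assert deleted["variant_residue"].isna().all()
    assert deleted["sigma"].isna().all()
    present = truth[truth["reference_residue"] == 510]
    assert int(present["variant_residue"].iloc[0]) == 509
    assert float(present["sigma"].iloc[0]) == pytest.approx(spec.sigma_for(510))

    contacts = pd.read_csv(tmp_path / "truth_contacts.tsv", sep="\t")
    assert len(contacts) == len(spec.interface_contacts)


def test_spec_validation():
    with pytest.raises(ValueError, match="outside every domain"):
        GeneratorSpec(domains=(DomainLayout("A", 1, 10),), seed=1, deletion_position=99)
    with pytest.raises(ValueError, match="cross-domain"):
        GeneratorSpec(
            domains=(DomainLayout("A", 1, 10), DomainLayout("B", 21, 10, (1, 0))),
            seed=1,
            interface_contacts=(Contact(1, 2, -0.5),),
        )
    with pytest.raises(ValueError, match="negative"):
        GeneratorSpec(
            domains=(DomainLayout("A", 1, 10), DomainLayout("B", 21, 10, (1, 0))),
            seed=1,
            interface_contacts=(Contact(1, 21, 0.5),),
        )


def test_sigma_profile_overrides_and_multipliers():
    spec = GeneratorSpec(
        domains=(DomainLayout("A", 1, 10),),
        seed=1,
        base_sigma=0.4,
        sigma_profile=((3, 1.0),),
        hot_regions=(("h", HotRegion(2, 4, 2.0)),),
    )
    assert spec.sigma_for(1) == pytest.approx(0.4)
    assert spec.sigma_for(2) == pytest.approx(0.8)
    assert spec.sigma_for(3) == pytest.approx(2.0)  # override × multiplier
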