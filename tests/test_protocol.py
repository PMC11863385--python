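import numpy as np
import pytest

from pocketcv import (
    CVSeries,
    MetaDParams,
    SwitchingParams,
    apply_charged_split,
    build_binding_site_cvs,
    build_crd_cvs,
    build_protocol,
    build_restraint_schedule,
    emit_metadynamics_input,
    estimate_hill_widths,
    parse_metadynamics_input,
    select_interface_residues,
)
from pocketcv.cvs import CVDefinition
from pocketcv.protocol import render_deck
from pocketcv.structures import DomainMap, SiteDefinition

from conftest import make_structure


def two_domain_system(mobile_distances):
    """CORE residues at the origin region; mobile residues at given
    minimum distances from the nearest CORE atom."""
    atoms = [("CA", "C", "A:1", "GLY", (0.0, 0.0, 0.0)),
             ("CA", "C", "A:2", "GLY", (3.8, 0.0, 0.0))]
    mapping = {"A:1": "CORE", "A:2": "CORE"}
    for i, d in enumerate(mobile_distances, start=10):
        atoms.append(("CA", "C", f"A:{i}", "GLY", (0.0, float(d), 0.0)))
        mapping[f"A:{i}"] = "LID"
    return make_structure(atoms), DomainMap(mapping)


class TestInterfaceSelection:
    def test_distance_rule(self):
        s, domains = two_domain_system([7.0, 9.0])
        site = SiteDefinition(("A:1", "A:2", "A:10", "A:11"))
        out = select_interface_residues(s, site, domains, "LID", "CORE")
        assert "A:10" in out and "A:11" not in out

    def test_infinite_cutoff_takes_all_site_residues_of_both_domains(self):
        s, domains = two_domain_system([7.0, 9.0, 30.0])
        site = SiteDefinition(("A:1", "A:10", "A:11", "A:12"))
        out = select_interface_residues(s, site, domains, "LID", "CORE",
                                        cutoff=np.inf)
        assert set(out) == set(site.residues)

    def test_empty_interface_suggests_larger_cutoff(self):
        s, domains = two_domain_system([30.0])
        site = SiteDefinition(("A:10",))
        with pytest.raises(ValueError, match="larger cutoff"):
            select_interface_residues(s, site, domains, "LID", "CORE")

    def test_interfaces_disjoint_on_toy(self, toy):
        lid = select_interface_residues(toy.structure, toy.site, toy.domains,
                                        "LID", "CORE")
        nmp = select_interface_residues(toy.structure, toy.site, toy.domains,
                                        "NMP", "CORE")
        assert set(lid).isdisjoint(nmp)
        assert set(lid) <= set(toy.site.residues)
        assert set(nmp) <= set(toy.site.residues)


class TestCrdConstruction:
    def test_toy_yields_two_disjoint_crds(self, toy):
        crds, _audit = build_crd_cvs(toy.structure, toy.site, toy.domains)
        assert [cv.name for cv in crds] == ["crd_lid", "crd_nmp"]
        all_res = [r for cv in crds for r in (*cv.residues_a, *cv.residues_b)]
        assert len(all_res) == len(set(all_res))
        for cv in crds:
            assert len(cv.residues_a) >= 4 and len(cv.residues_b) >= 4

    def test_single_domain_warns_empty(self, toy):
        single = DomainMap({r: "CORE" for r in toy.domains.mapping})
        with pytest.warns(UserWarning, match="single-domain"):
            crds, _ = build_crd_cvs(toy.structure, toy.site, single)
        assert crds == []

    def test_too_few_residues_per_side_errors(self):
        s, domains = two_domain_system([5.0, 6.0, 7.0])
        site = SiteDefinition(("A:1", "A:2", "A:10", "A:11", "A:12"))
        with pytest.raises(ValueError, match="minimum 4"):
            build_crd_cvs(s, site, domains)


def _crd_from_residues(structure, res_a, res_b):
    return CVDefinition(
        name="crd_x", kind="CRD",
        group_a=structure.heavy_indices(res_a),
        group_b=structure.heavy_indices(res_b),
        switching=SwitchingParams(),
        residues_a=tuple(res_a), residues_b=tuple(res_b),
    )


class TestChargedSplit:
    def _system(self):
        # side A: residues 1-4, side B: residues 11-14, alternating charge
        atoms = []
        names = {1: "ASP", 2: "GLY", 3: "LYS", 4: "ALA",
                 11: "GLU", 12: "SER", 13: "ARG", 14: "LEU"}
        for i, name in names.items():
            atoms.append(("CA", "C", f"A:{i}", name, (float(i), 0.0, 0.0)))
        s = make_structure(atoms)
        charged = [f"A:{i}" for i in (1, 3, 11, 13)]
        cv = _crd_from_residues(s, [f"A:{i}" for i in (1, 2, 3, 4)],
                                [f"A:{i}" for i in (11, 12, 13, 14)])
        return s, cv, charged

    def test_split_applied_above_threshold(self):
        s, cv, charged = self._system()
        out, decision = apply_charged_split(s, cv, charged,
                                            site_charged_fraction=11 / 32)
        assert [c.name for c in out] == ["crd_xc", "crd_xo"]
        assert "split into" in decision
        # split preserves the union of atoms
        before = set(cv.group_a) | set(cv.group_b)
        after = set().union(*[set(c.group_a) | set(c.group_b) for c in out])
        assert before == after

    def test_no_split_below_threshold(self):
        s, cv, charged = self._system()
        out, decision = apply_charged_split(s, cv, charged,
                                            site_charged_fraction=2 / 32)
        assert out == [cv] and "not split" in decision

    def test_no_split_when_charged_residues_adjacent(self):
        # 28% overall but charged residues form a single adjacent pair
        atoms = []
        names = {1: "ASP", 2: "GLU", 3: "GLY", 4: "ALA",
                 11: "LYS", 12: "ARG", 13: "SER", 14: "LEU"}
        for i, name in names.items():
            atoms.append(("CA", "C", f"A:{i}", name, (float(i), 0.0, 0.0)))
        s = make_structure(atoms)
        cv = _crd_from_residues(s, [f"A:{i}" for i in (1, 2, 3, 4)],
                                [f"A:{i}" for i in (11, 12, 13, 14)])
        out, decision = apply_charged_split(
            s, cv, [f"A:{i}" for i in (1, 2, 11, 12)],
            site_charged_fraction=0.28)
        assert out == [cv]
        assert "non-adjacent" in decision


class TestHillWidths:
    def _series(self, cols, n=41, dt=5.0, seed=9):
        rng = np.random.default_rng(seed)
        values = np.column_stack([rng.normal(0, s, n) for s in cols])
        return CVSeries(values=values, names=[f"cv{i}" for i in range(len(cols))],
                        times=np.arange(n) * dt)

    def test_constant_column_errors(self):
        series = CVSeries(values=np.ones((50, 1)), names=["cv0"],
                          times=np.arange(50) * 5.0)
        with pytest.raises(ValueError, match="constant"):
            estimate_hill_widths(series)

    def test_recovers_known_sigma(self):
        widths = estimate_hill_widths(self._series([0.3]))
        assert widths["cv0"] == pytest.approx(0.3, rel=0.25)

    def test_width_ratio_follows_sigma_ratio(self):
        widths = estimate_hill_widths(self._series([0.4, 0.2]))
        assert widths["cv0"] / widths["cv1"] == pytest.approx(2.0, rel=0.3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            estimate_hill_widths(self._series([0.3], n=10, dt=5.0))


class TestRestraintSchedule:
    @pytest.fixture()
    def schedule(self):
        return build_restraint_schedule(rog_apo=20.0)

    def test_phase_boundaries(self, schedule):
        assert schedule.k_at(5.0) == 0.0                      # unrestrained
        assert schedule.center_at(5.0) is None
        assert schedule.k_at(50.0) == pytest.approx(25.0)     # end of ramp
        assert schedule.k_at(30.0) == pytest.approx(17.5)     # mid-ramp
        assert schedule.center_at(450.0) == pytest.approx(0.85 * 20.0)
        assert schedule.center_at(250.0) == pytest.approx(0.925 * 20.0)
        assert schedule.center_at(600.0) == pytest.approx(17.0)

    def test_center_non_increasing_and_continuous(self, schedule):
        ts = np.linspace(10.01, 600.0, 1200)
        centers = np.array([schedule.center_at(t) for t in ts])
        assert np.all(np.diff(centers) <= 1e-9)
        assert np.max(np.abs(np.diff(centers))) < 0.1  # no jumps beyond 1 step

    def test_stepwise_descent(self, schedule):
        # center is constant within each 1 ns step of the descent phase
        assert schedule.center_at(100.2) == schedule.center_at(100.8)
        assert schedule.center_at(101.0) <= schedule.center_at(100.9)

    def test_invalid_target_fraction(self):
        with pytest.raises(ValueError):
            build_restraint_schedule(20.0, target_fraction=1.5)


@pytest.fixture(scope="module")
def bundle(toy, unbiased_traj):
    return build_protocol(toy.structure, toy.site, toy.domains,
                          unbiased_trajectory=unbiased_traj)


class TestDeckEmission:
    def test_pace_conversion(self, bundle):
        deck = emit_metadynamics_input(bundle, timestep_fs=2.0)
        assert "PACE=1250" in deck  # 2.5 ps / 2 fs

    def test_headline_parameters_present(self, bundle):
        deck = emit_metadynamics_input(bundle, timestep_fs=2.0)
        assert "HEIGHT=0.6" in deck
        assert "BIASFACTOR=10" in deck
        assert "VERSE=U" in deck

    def test_non_integer_pace_errors(self, bundle):
        with pytest.raises(ValueError, match="timestep"):
            emit_metadynamics_input(bundle, timestep_fs=3.0)

    def test_emit_parse_emit_is_byte_identical(self, bundle):
        deck = emit_metadynamics_input(bundle, timestep_fs=2.0)
        assert render_deck(parse_metadynamics_input(deck)) == deck

    def test_deterministic_given_same_inputs(self, toy, unbiased_traj):
        b1 = build_protocol(toy.structure, toy.site, toy.domains,
                            unbiased_trajectory=unbiased_traj)
        b2 = build_protocol(toy.structure, toy.site, toy.domains,
                            unbiased_trajectory=unbiased_traj)
        assert emit_metadynamics_input(b1) == emit_metadynamics_input(b2)
        assert b1.audit == b2.audit

    def test_parsed_deck_recovers_parameters(self, bundle):
        deck = parse_metadynamics_input(emit_metadynamics_input(bundle))
        metad = deck.directive("METAD")
        assert float(metad["HEIGHT"]) == 0.6
        assert float(metad["BIASFACTOR"]) == 10.0
        assert int(metad["PACE"]) == 1250
        restraint = deck.directive("MOVINGRESTRAINT")
        target = bundle.schedule.target_fraction * bundle.schedule.rog_apo
        assert float(restraint["AT2"]) == pytest.approx(target, rel=1e-4)
        assert float(restraint["KAPPA1"]) == 25.0

    def test_missing_widths_rejected(self, toy):
        bundle = build_protocol(toy.structure, toy.site, toy.domains,
                                metad=MetaDParams())
        with pytest.raises(ValueError, match="width"):
            emit_metadynamics_input(bundle)

    def test_audit_records_split_decisions(self, bundle):
        assert any("split into crd_lidc/crd_lido" in a for a in bundle.audit)
        assert any("34.4%" in a for a in bundle.audit)


def test_build_binding_site_cvs_counts(toy):
    rog, cips, _frame, _ = build_binding_site_cvs(toy.structure, toy.site)
    assert rog.kind == "ROG" and len(cips) == 3
    bb_names = set(toy.structure.atom_names[rog.group_a])
    assert bb_names == {"N", "CA", "C", "O"}
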