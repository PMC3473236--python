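import numpy as np
import pytest

from decoybench.annotations import CatalyticSite, DecoyMeta, DecoySet
from decoybench.benchmarks import (
    RecoveryResult,
    bin_and_summarize,
    cavity_recovery,
    default_bin_edges,
    exposure_recovery,
    run_benchmark,
    site_distance_difference,
    DecoyBenchmarkRow,
)
from decoybench.sasa import ExposureClass, SasaParams, SasaProfile
from decoybench.structure_io import AtomRecord, ChainStructure, Residue, ResidueId

from conftest import apply_rigid, rigid_transform


def profile_from_classes(classes: dict[int, str]) -> SasaProfile:
    params = SasaParams()
    cls = {ResidueId("A", k): ExposureClass(v) for k, v in classes.items()}
    return SasaProfile(
        per_residue_abs={k: 0.0 for k in cls},
        per_residue_rel={k: 0.0 for k in cls},
        exposure_class=cls,
        params=params,
    )


class TestExposureRecovery:
    def test_three_of_four_is_exact_boundary_success(self):
        native = profile_from_classes(
            {1: "exposed", 2: "exposed", 3: "exposed", 4: "exposed"}
        )
        model = profile_from_classes(
            {1: "exposed", 2: "exposed", 3: "exposed", 4: "buried", 9: "exposed"}
        )
        r = exposure_recovery(native, model, "exposed")
        assert r.fraction == pytest.approx(0.75)
        assert r.success is True  # "at least 75%" is inclusive

    def test_identity_recovers_everything(self):
        native = profile_from_classes({1: "exposed", 2: "buried", 3: "exposed"})
        r = exposure_recovery(native, native, "exposed")
        assert r.fraction == 1.0 and r.success

    def test_all_reclassified_gives_zero(self):
        native = profile_from_classes({1: "exposed", 2: "exposed"})
        model = profile_from_classes({1: "intermediate", 2: "intermediate"})
        r = exposure_recovery(native, model, "exposed")
        assert r.fraction == 0.0 and r.success is False

    def test_empty_reference_flagged(self):
        native = profile_from_classes({1: "buried"})
        r = exposure_recovery(native, native, "exposed")
        assert r.fraction is None and r.success is None and not r.assessable

    def test_native_residue_missing_from_model_counts_against(self):
        native = profile_from_classes({1: "exposed", 2: "exposed"})
        model = profile_from_classes({1: "exposed"})
        assert exposure_recovery(native, model, "exposed").fraction == 0.5

    def test_mismatched_thresholds_rejected(self):
        native = profile_from_classes({1: "exposed"})
        model = profile_from_classes({1: "exposed"})
        model.params = SasaParams(exposed_threshold=80.0)
        with pytest.raises(ValueError):
            exposure_recovery(native, model, "exposed")


class TestCavityRecovery:
    def test_identity_full_recovery(self, pocket_small):
        r = cavity_recovery(pocket_small, pocket_small)
        assert r.fraction == 1.0 and r.success

    def test_collapsed_void_recovers_nothing(self, pocket_small):
        # pull every atom toward the centre: the void disappears
        from copy import deepcopy

        collapsed = deepcopy(pocket_small)
        for res in collapsed.residues:
            for a in res.atoms:
                a.coord = a.coord * 0.45
        r = cavity_recovery(pocket_small, collapsed)
        assert r.fraction == 0.0 and r.success is False

    def test_counts_arithmetic(self):
        r = RecoveryResult.from_counts(8, 6)
        assert r.fraction == pytest.approx(0.75) and r.success


def ca_only_chain(coords):
    return ChainStructure(
        [
            Residue(ResidueId("A", i + 1), "ALA",
                    [AtomRecord(i + 1, "CA", "C", np.asarray(c, float))])
            for i, c in enumerate(coords)
        ]
    )


class TestSiteDistance:
    def site(self, nums):
        return CatalyticSite("S1", [(ResidueId("A", n), "ALA") for n in nums])

    def test_identity_zero(self, helix10):
        r = site_distance_difference(helix10, helix10, self.site([1, 4, 7]))
        assert r.mean_diff == 0.0

    def test_three_four_five_worked_example(self):
        # native pair distances (3,4,5); model (3,4,6) -> diffs (0,0,1), mean 1/3
        native = ca_only_chain([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        x = -11.0 / 6.0  # places the third point 4 from r1 and 6 from r2
        model = ca_only_chain([[0, 0, 0], [3, 0, 0], [x, np.sqrt(16 - x * x), 0]])
        r = site_distance_difference(native, model, self.site([1, 2, 3]))
        d = np.linalg.norm(model.residues[2].atoms[0].coord
                           - model.residues[1].atoms[0].coord)
        assert d == pytest.approx(6.0, abs=1e-6)  # construction check
        assert r.mean_diff == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_rigid_motion_invariance(self, helix20):
        from decoybench import PerturbationParams, perturb_structure

        model = perturb_structure(helix20, PerturbationParams(amplitude=2.0, seed=1))
        site = self.site([2, 8, 15])
        base = site_distance_difference(helix20, model, site).mean_diff
        rng = np.random.default_rng(5)
        R, t = rigid_transform(rng)
        moved = apply_rigid(model, R, t)
        assert site_distance_difference(helix20, moved, site).mean_diff == \
            pytest.approx(base, abs=1e-9)

    def test_too_few_usable_residues_raises(self, helix10):
        with pytest.raises(ValueError, match="S1"):
            site_distance_difference(helix10, helix10, self.site([1, 99]))


def make_row(decoy_id, g, exp_success=True, site_mean=None):
    def rr(success):
        return RecoveryResult(4, 3 if success else 1,
                              0.75 if success else 0.25, success)

    sites = []
    if site_mean is not None:
        from decoybench.benchmarks import SiteDistanceResult

        sites = [SiteDistanceResult("S1", {}, site_mean)]
    return DecoyBenchmarkRow(
        decoy_id=decoy_id, gdt_ts=g, rmsd=1.0,
        exposed=rr(exp_success), buried=rr(True), cavity=rr(True), sites=sites,
    )


class TestBinning:
    def test_half_success_is_fifty_percent(self):
        rows = [make_row("a", 95.0, True), make_row("b", 92.0, False)]
        s = bin_and_summarize(rows)["exposed"]
        assert s.pct_success[(90.0, 100.0)] == pytest.approx(50.0)

    def test_counts_conserved_across_bins(self):
        rng = np.random.default_rng(0)
        rows = [make_row(str(i), float(g)) for i, g in
                enumerate(rng.uniform(0, 100, size=25))]
        s = bin_and_summarize(rows)["cavity"]
        assert sum(s.n_models.values()) == 25

    def test_boundary_100_lands_in_top_bin(self):
        s = bin_and_summarize([make_row("x", 100.0)])["exposed"]
        assert s.n_models[(90.0, 100.0)] == 1

    def test_mean_never_exceeds_max(self):
        rows = [make_row("a", 55.0, site_mean=0.2),
                make_row("b", 57.0, site_mean=0.8)]
        s = bin_and_summarize(rows)["site_distance"]
        b = (50.0, 60.0)
        assert s.mean_of_means[b] <= s.max_of_means[b]
        assert s.mean_of_means[b] == pytest.approx(0.5)

    def test_empty_bins_have_zero_models_and_no_stats(self):
        s = bin_and_summarize([])["exposed"]
        assert all(v == 0 for v in s.n_models.values())
        assert all(v is None for v in s.pct_success.values())


class TestRunBenchmark:
    def test_native_as_decoy_is_perfect(self, pocket_small):
        from decoybench.structure_io import ca_trace

        trace = ca_trace(pocket_small)
        site = CatalyticSite("S1", [(trace[i][0], "ALA") for i in (0, 4, 8)])
        ds = DecoySet(native=pocket_small, decoys=[pocket_small],
                      meta=[DecoyMeta(decoy_id="self")])
        report = run_benchmark(ds, sites=[site])
        row = report.rows[0]
        assert row.gdt_ts == 100.0
        assert row.rmsd == pytest.approx(0.0, abs=1e-9)
        assert row.exposed.fraction == 1.0
        assert row.cavity.fraction == 1.0
        assert row.sites[0].mean_diff == 0.0
        assert report.summaries["exposed"].pct_success[(90.0, 100.0)] == 100.0

    def test_empty_decoy_list_gives_empty_valid_report(self, pocket_small):
        report = run_benchmark(DecoySet(native=pocket_small), with_cavity=False)
        assert report.rows == []
        assert all(v == 0 for v in report.summaries["exposed"].n_models.values())

    def test_row_count_matches_decoys_and_errors_collected(self, helix20, helix10):
        # second decoy shares no residues 11-20 information but still scores;
        # third decoy is broken (no CA overlap) and must not abort the run
        broken = ca_only_chain([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        for r in broken.residues:
            r.id = ResidueId("Z", r.id.seq_num + 500)
        ds = DecoySet(native=helix20, decoys=[helix20, helix10, broken],
                      meta=[DecoyMeta(decoy_id=f"d{i}") for i in range(3)])
        report = run_benchmark(ds, with_cavity=False)
        assert len(report.rows) == 3
        assert report.rows[2].error is not None

    def test_report_serialization_round_trip_shapes(self, pocket_small):
        import json

        ds = DecoySet(native=pocket_small, decoys=[pocket_small],
                      meta=[DecoyMeta(decoy_id="self")])
        report = run_benchmark(ds, with_cavity=False)
        tsv = report.to_tsv()
        assert len(tsv.strip().splitlines()) == 2
        payload = json.loads(report.to_json())
        assert payload["rows"][0]["decoy_id"] == "self"
        assert "summaries" in payload
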