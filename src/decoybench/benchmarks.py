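"""The three structure-based usefulness benchmarks, per decoy and GDT-binned.

For a native structure and a set of decoy models of graded accuracy, this
module measures how well each model preserves

1. the exposed/buried classification of residues (Miller-relative solvent
   accessibility above 70% / below 30%): the fraction of the native's
   exposed (resp. buried) residues that receive the same class in the
   model, success meaning at least 75% recovered;
2. the largest surface cavity: the fraction of the residues lining the
   native's largest cavity that also line the model's largest cavity
   (a residue belongs to a cavity if any of its atoms does), success
   again at 75%;
3. catalytic-site geometry: for every unordered pair of catalytic-residue
   Ca atoms within a site of two or more residues, the absolute
   difference between the native and model Ca-Ca distances, averaged over
   the site.  Internal distances make this superposition-free and
   rigid-motion invariant.  (Enumerating ordered permutations would count
   each symmetric difference twice and leave the mean unchanged.)

Per-decoy results are summarised in GDT-TS decade bins [0,10), ..., [90,100]:
percentage of successful models per bin for the recovery benchmarks, and
the mean and maximum of per-site mean differences for the site benchmark.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from decoybench.annotations import CatalyticSite, DecoyMeta, DecoySet
from decoybench.cavity import GridSpec, detect_cavities
from decoybench.sasa import ExposureClass, SasaParams, SasaProfile, sasa_profile
from decoybench.structure_io import ChainStructure, ResidueId, ca_trace
from decoybench.superposition import gdt_ts, kabsch_superpose

__all__ = [
    "RECOVERY_SUCCESS_THRESHOLD",
    "RecoveryResult",
    "SiteDistanceResult",
    "BinnedSummary",
    "DecoyBenchmarkRow",
    "BenchmarkReport",
    "exposure_recovery",
    "cavity_recovery",
    "site_distance_difference",
    "bin_and_summarize",
    "run_benchmark",
    "default_bin_edges",
]

RECOVERY_SUCCESS_THRESHOLD = 0.75  # "at least 75% ... correctly identified"


@dataclass
class RecoveryResult:
    """How much of a native reference residue set a model recovers."""

    n_reference: int
    n_recovered: int
    fraction: float | None  # None when the reference set is empty
    success: bool | None
    assessable: bool = True

    @classmethod
    def from_counts(cls, n_reference: int, n_recovered: int) -> "RecoveryResult":
        if n_reference == 0:
            return cls(0, 0, None, None, assessable=False)
        frac = n_recovered / n_reference
        return cls(n_reference, n_recovered, frac, frac >= RECOVERY_SUCCESS_THRESHOLD)


@dataclass
class SiteDistanceResult:
    site_id: str
    per_pair_diff: dict[tuple[ResidueId, ResidueId], float]
    mean_diff: float


@dataclass
class BinnedSummary:
    """Per-GDT-bin aggregate of one benchmark quantity."""

    name: str
    bin_edges: list[tuple[float, float]]
    n_models: dict[tuple[float, float], int]
    pct_success: dict[tuple[float, float], float | None] = field(default_factory=dict)
    mean_of_means: dict[tuple[float, float], float | None] = field(default_factory=dict)
    max_of_means: dict[tuple[float, float], float | None] = field(default_factory=dict)


@dataclass
class DecoyBenchmarkRow:
    decoy_id: str
    gdt_ts: float
    rmsd: float
    exposed: RecoveryResult
    buried: RecoveryResult
    cavity: RecoveryResult
    sites: list[SiteDistanceResult]
    error: str | None = None

    @property
    def mean_site_diff(self) -> float | None:
        if not self.sites:
            return None
        return float(np.mean([s.mean_diff for s in self.sites]))


@dataclass
class BenchmarkReport:
    rows: list[DecoyBenchmarkRow]
    summaries: dict[str, BinnedSummary]

    def to_tsv(self) -> str:
        header = [
            "decoy_id", "gdt_ts", "rmsd",
            "exp_frac", "exp_success", "bur_frac", "bur_success",
            "cav_frac", "cav_success", "site_mean_diffs",
        ]
        lines = ["\t".join(header)]
        for r in self.rows:
            def frac(rr: RecoveryResult) -> str:
                return "NA" if rr.fraction is None else f"{rr.fraction:.4f}"

            def succ(rr: RecoveryResult) -> str:
                return "NA" if rr.success is None else str(rr.success).lower()

            sites = ";".join(f"{s.site_id}={s.mean_diff:.4f}" for s in r.sites)
            lines.append(
                "\t".join(
                    [
                        r.decoy_id, f"{r.gdt_ts:.2f}", f"{r.rmsd:.3f}",
                        frac(r.exposed), succ(r.exposed),
                        frac(r.buried), succ(r.buried),
                        frac(r.cavity), succ(r.cavity),
                        sites or "NA",
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        def bin_key(b: tuple[float, float]) -> str:
            return f"[{b[0]:g},{b[1]:g}]"

        payload = {
            "rows": [
                {
                    "decoy_id": r.decoy_id,
                    "gdt_ts": r.gdt_ts,
                    "rmsd": r.rmsd,
                    "exposed": vars(r.exposed),
                    "buried": vars(r.buried),
                    "cavity": vars(r.cavity),
                    "sites": [
                        {"site_id": s.site_id, "mean_diff": s.mean_diff}
                        for s in r.sites
                    ],
                    "error": r.error,
                }
                for r in self.rows
            ],
            "summaries": {
                name: {
                    bin_key(b): {
                        "n_models": s.n_models[b],
                        **(
                            {"pct_success": s.pct_success.get(b)}
                            if s.pct_success
                            else {}
                        ),
                        **(
                            {
                                "mean_of_means": s.mean_of_means.get(b),
                                "max_of_means": s.max_of_means.get(b),
                            }
                            if s.mean_of_means
                            else {}
                        ),
                    }
                    for b in s.bin_edges
                }
                for name, s in self.summaries.items()
            },
        }
        return json.dumps(payload, indent=2)


def default_bin_edges() -> list[tuple[float, float]]:
    """GDT-TS decade bins, left-closed, with [90, 100] closed on both ends."""
    return [(10.0 * i, 10.0 * (i + 1)) for i in range(10)]


def _in_bin(value: float, bin_: tuple[float, float]) -> bool:
    lo, hi = bin_
    if hi >= 100.0:
        return lo <= value <= hi
    return lo <= value < hi


def exposure_recovery(
    native_profile: SasaProfile,
    model_profile: SasaProfile,
    which: ExposureClass | str,
) -> RecoveryResult:
    """Recovery of the native's exposed (or buried) residues by a model.

    Restricted to residues classified in both profiles; native residues
    absent from the model count against recovery.  Profiles must share
    classification thresholds.
    """
    which = ExposureClass(which)
    np_, mp = native_profile.params, model_profile.params
    if (np_.exposed_threshold, np_.buried_threshold) != (
        mp.exposed_threshold,
        mp.buried_threshold,
    ):
        raise ValueError("native and model profiles use different thresholds")
    reference = native_profile.residues_of_class(which)
    model_same = model_profile.residues_of_class(which)
    recovered = reference & model_same
    return RecoveryResult.from_counts(len(reference), len(recovered))


def cavity_recovery(
    native: ChainStructure,
    model: ChainStructure,
    grid: GridSpec | None = None,
    sasa_params: SasaParams | None = None,
    native_cavities=None,
) -> RecoveryResult:
    """Recovery of the native's largest-cavity residues by the model's largest cavity.

    If the model yields no cavity the fraction is 0; if the *native* has
    no cavity the benchmark is flagged not assessable.  Pre-computed
    ``native_cavities`` may be passed to avoid repeated detection.
    """
    if native_cavities is None:
        native_cavities = detect_cavities(native, grid, sasa_params)
    if not native_cavities:
        return RecoveryResult(0, 0, None, None, assessable=False)
    reference = native_cavities[0].residues
    model_cavities = detect_cavities(model, grid, sasa_params)
    if not model_cavities:
        return RecoveryResult.from_counts(len(reference), 0)
    recovered = reference & model_cavities[0].residues
    return RecoveryResult.from_counts(len(reference), len(recovered))


def site_distance_difference(
    native: ChainStructure, model: ChainStructure, site: CatalyticSite
) -> SiteDistanceResult:
    """Absolute native-vs-model differences of catalytic Ca-Ca distances.

    Uses every unordered pair of the site's residues that have a Ca in
    both structures; the site must retain at least two such residues.
    The result depends only on internal distances, hence is invariant
    under rigid motion of either structure.
    """
    nat_ca = dict(ca_trace(native))
    mod_ca = dict(ca_trace(model))
    usable = [
        rid for rid in site.residue_ids if rid in nat_ca and rid in mod_ca
    ]
    if len(usable) < 2:
        raise ValueError(
            f"site {site.site_id}: fewer than 2 residues with CA in both structures"
        )
    diffs: dict[tuple[ResidueId, ResidueId], float] = {}
    for a, b in combinations(usable, 2):
        dn = float(np.linalg.norm(nat_ca[a] - nat_ca[b]))
        dm = float(np.linalg.norm(mod_ca[a] - mod_ca[b]))
        diffs[(a, b)] = abs(dn - dm)
    return SiteDistanceResult(
        site_id=site.site_id,
        per_pair_diff=diffs,
        mean_diff=float(np.mean(list(diffs.values()))),
    )


def bin_and_summarize(
    rows: list[DecoyBenchmarkRow],
    bin_edges: list[tuple[float, float]] | None = None,
) -> dict[str, BinnedSummary]:
    """Aggregate per-decoy results into GDT-TS decade bins.

    Produces four summaries: exposed/buried/cavity success percentages and
    site distance statistics (mean and max over models of per-site means).
    """
    bins = bin_edges or default_bin_edges()
    summaries: dict[str, BinnedSummary] = {}
    membership = {
        b: [r for r in rows if _in_bin(r.gdt_ts, b)] for b in bins
    }

    for name, getter in (
        ("exposed", lambda r: r.exposed),
        ("buried", lambda r: r.buried),
        ("cavity", lambda r: r.cavity),
    ):
        s = BinnedSummary(name=name, bin_edges=bins, n_models={}, pct_success={})
        for b, members in membership.items():
            assessed = [r for r in members if getter(r).success is not None]
            s.n_models[b] = len(members)
            s.pct_success[b] = (
                100.0 * sum(getter(r).success for r in assessed) / len(assessed)
                if assessed
                else None
            )
        summaries[name] = s

    s = BinnedSummary(
        name="site_distance", bin_edges=bins, n_models={},
        mean_of_means={}, max_of_means={},
    )
    for b, members in membership.items():
        site_means = [
            m for r in members if (m := r.mean_site_diff) is not None
        ]
        s.n_models[b] = len(members)
        s.mean_of_means[b] = float(np.mean(site_means)) if site_means else None
        s.max_of_means[b] = float(np.max(site_means)) if site_means else None
    summaries["site_distance"] = s
    return summaries


def _quality_scores(
    native: ChainStructure, model: ChainStructure
) -> tuple[float, float]:
    nat = dict(ca_trace(native))
    mod = dict(ca_trace(model))
    common = [rid for rid in nat if rid in mod]
    ref = np.array([nat[r] for r in common])
    mov = np.array([mod[r] for r in common])
    g = gdt_ts(native, model)
    sup = kabsch_superpose(ref, mov)
    return g.gdt_ts, sup.rmsd


def run_benchmark(
    decoy_set: DecoySet,
    sites: list[CatalyticSite] | None = None,
    sasa_params: SasaParams | None = None,
    grid: GridSpec | None = None,
    bin_edges: list[tuple[float, float]] | None = None,
    with_cavity: bool = True,
) -> BenchmarkReport:
    """Run all three benchmarks on a decoy set and summarise by GDT bin.

    Native-side quantities (SASA profile, cavity detection) are computed
    once and reused; a failure on one decoy is recorded in its row's
    ``error`` field without aborting the run.
    """
    sites = [s for s in (sites or []) if s.eligible_for_distance_analysis]
    sasa_params = sasa_params or SasaParams()
    native = decoy_set.native
    native_profile = sasa_profile(native, sasa_params)
    native_cavities = detect_cavities(native, grid, sasa_params) if with_cavity else []

    rows: list[DecoyBenchmarkRow] = []
    for i, decoy in enumerate(decoy_set.decoys):
        meta = decoy_set.meta[i] if i < len(decoy_set.meta) else DecoyMeta()
        decoy_id = meta.decoy_id or f"decoy_{i:03d}"
        error = None
        try:
            score, rmsd = _quality_scores(native, decoy)
            model_profile = sasa_profile(decoy, sasa_params)
            exposed = exposure_recovery(
                native_profile, model_profile, ExposureClass.EXPOSED
            )
            buried = exposure_recovery(
                native_profile, model_profile, ExposureClass.BURIED
            )
            if with_cavity:
                cav = cavity_recovery(
                    native, decoy, grid, sasa_params, native_cavities=native_cavities
                )
            else:
                cav = RecoveryResult(0, 0, None, None, assessable=False)
            site_results = []
            for site in sites:
                try:
                    site_results.append(site_distance_difference(native, decoy, site))
                except ValueError as exc:
                    error = str(exc)
        except (ValueError, KeyError) as exc:
            rows.append(
                DecoyBenchmarkRow(
                    decoy_id=decoy_id, gdt_ts=math.nan, rmsd=math.nan,
                    exposed=RecoveryResult(0, 0, None, None, False),
                    buried=RecoveryResult(0, 0, None, None, False),
                    cavity=RecoveryResult(0, 0, None, None, False),
                    sites=[], error=str(exc),
                )
            )
            continue
        rows.append(
            DecoyBenchmarkRow(
                decoy_id=decoy_id, gdt_ts=score, rmsd=rmsd,
                exposed=exposed, buried=buried, cavity=cav,
                sites=site_results, error=error,
            )
        )
    ok_rows = [r for r in rows if not math.isnan(r.gdt_ts)]
    return BenchmarkReport(rows=rows, summaries=bin_and_summarize(ok_rows, bin_edges))
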