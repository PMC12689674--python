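"""Nonparametric comparisons and the virtual-study orchestrator.

The three rank tests used in this kind of accuracy study — Friedman for
paired factor comparisons, Wilcoxon signed-rank for the two-instrument
pairing, Kruskal-Wallis for independent groups — are implemented from
their formulas (mid-ranks, tie corrections, exact Wilcoxon enumeration
for small n). ``run_study`` drives the whole pipeline over the factorial
design and reproduces the analysis structure of the study: slot-design,
instrument, guide-height, per-segment and U-distance comparisons.
"""

from __future__ import annotations

import itertools as _itertools
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from . import reconstruction as recon
from .cutplane import cut_faces_from_labels, detect_cut_faces
from .mesh_core import OsteoguideError, write_ply_scalar
from .segment_metrics import measure_segment, plane_angle
from .synthetic_fibula import (
    StudyDesign,
    build_segments,
    make_plan,
    perturb_plan,
)

__all__ = [
    "TestResult",
    "SummaryRow",
    "friedman_test",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "summarize",
    "run_study",
    "StudyResult",
]

log = logging.getLogger(__name__)

EXACT_WILCOXON_LIMIT = 20   # 2^20 sign patterns; enumeration stays ~1e6


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    method: str                 # 'exact' | 'approximate'
    n: int
    df: int | None = None
    ties: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SummaryRow:
    group: dict
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float


# ---------------------------------------------------------------------------
# Rank tests (from formulas)
# ---------------------------------------------------------------------------

_EXACT_FRIEDMAN_LIMIT = 250_000     # max enumerated within-block permutations
_MC_PERMUTATIONS = 200_000
_MC_SEED = 987_654_321              # fixed internal stream, results reproducible


def _friedman_stat(ranks: np.ndarray) -> tuple[float, float]:
    """(between-treatment rank SS, total rank variance) of a rank matrix."""
    n, k = ranks.shape
    rbar = (k + 1) / 2.0
    ss_treat = n * np.sum((ranks.mean(axis=0) - rbar) ** 2)
    ss_total = np.sum((ranks - rbar) ** 2) / (n * (k - 1))
    return ss_treat, ss_total


def friedman_test(matrix, method: str = "auto") -> TestResult:
    """Friedman test on an (n blocks x k treatments) matrix.

    Within-block mid-ranks; the tie-corrected statistic is the ratio of
    the between-treatment rank sum of squares to the total rank
    variance. The reference distribution depends on sample size: for
    small designs all within-block rank permutations are enumerated
    (exact p); for moderate ones a seeded Monte-Carlo permutation null
    is used; at study scale the chi-square(k - 1) approximation is
    accurate and fast. ``method`` forces one of
    ``exact | permutation | chisq``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2, k >= 2) complete matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    ranks = np.apply_along_axis(rankdata, 1, x)
    ties = bool(np.unique(ranks).size < ranks.size or (ranks != np.round(ranks)).any())
    ss_treat, ss_total = _friedman_stat(ranks)
    if ss_total <= 0:
        return TestResult("friedman", 0.0, 1.0, "approximate", n, df=k - 1,
                          ties=True, degenerate=True)
    stat = float(ss_treat / ss_total)

    block_rows = [np.array(sorted(set(_itertools.permutations(row))), dtype=float)
                  for row in ranks]
    n_exact = math.prod(len(b) for b in block_rows)
    if method == "auto":
        if n_exact <= _EXACT_FRIEDMAN_LIMIT:
            method = "exact"
        elif n * k <= 80:
            method = "permutation"
        else:
            method = "chisq"

    rbar = (k + 1) / 2.0
    if method == "exact":
        colsums = np.zeros((1, k))
        for rows in block_rows:
            colsums = (colsums[:, None, :] + rows[None, :, :]).reshape(-1, k)
        null_ss = n * np.sum((colsums / n - rbar) ** 2, axis=1)
        p = float(np.mean(null_ss / ss_total >= stat - 1e-12))
        return TestResult("friedman", stat, p, "exact", n, df=k - 1, ties=ties)
    if method == "permutation":
        rng = np.random.default_rng(_MC_SEED)
        count = 0
        done = 0
        while done < _MC_PERMUTATIONS:
            chunk = min(50_000, _MC_PERMUTATIONS - done)
            idx = np.argsort(rng.random((chunk, n, k)), axis=2)
            perm = np.take_along_axis(np.broadcast_to(ranks, (chunk, n, k)), idx, axis=2)
            null_ss = n * np.sum((perm.mean(axis=1) - rbar) ** 2, axis=1)
            count += int(np.sum(null_ss / ss_total >= stat - 1e-12))
            done += chunk
        p = count / _MC_PERMUTATIONS
        return TestResult("friedman", stat, p, "permutation", n, df=k - 1, ties=ties)
    p = float(chi2.sf(stat, k - 1))
    return TestResult("friedman", stat, p, "approximate", n, df=k - 1, ties=ties)


def _signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of W+ over all sign patterns (integer ranks)."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(differences, exact_limit: int = EXACT_WILCOXON_LIMIT) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are removed; W+ is the rank sum of the positive
    differences over mid-ranked |d|. For n <= ``exact_limit`` with no
    ties in |d| the p-value is exact (full enumeration of the 2^n sign
    patterns via the rank-sum distribution); otherwise a normal
    approximation with tie and continuity correction is used.
    """
    d = np.asarray(differences, dtype=float).ravel()
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon", 0.0, 1.0, "exact", 0, ties=True, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= exact_limit and not has_ties:
        dist = _signed_rank_distribution(ranks)
        w = int(round(w_plus))
        p_low = float(dist[: w + 1].sum())
        p_high = float(dist[w:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult("wilcoxon", w_plus, p, "exact", n)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts ** 3 - tie_counts) / 48.0
    if sigma2 <= 0:
        return TestResult("wilcoxon", w_plus, 1.0, "approximate", n,
                          ties=True, degenerate=True)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult("wilcoxon", w_plus, p, "approximate", n, ties=has_ties)


def kruskal_wallis(groups, method: str = "auto") -> TestResult:
    """Kruskal-Wallis H test over independent groups, with tie correction.

    For small pooled samples (N <= 30) the p-value comes from a seeded
    Monte-Carlo label-permutation null, where the chi-square(k - 1)
    approximation is unreliable; larger samples use chi-square.
    ``method`` forces ``permutation | chisq``.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    sizes = [len(g) for g in groups]
    ranks = rankdata(pooled)
    tie_counts = np.unique(pooled, return_counts=True)[1]
    correction = 1.0 - np.sum(tie_counts ** 3 - tie_counts) / (n_total ** 3 - n_total)
    ties = bool((tie_counts > 1).any())
    if correction <= 0:
        return TestResult("kruskal-wallis", 0.0, 1.0, "approximate", n_total,
                          df=len(groups) - 1, ties=True, degenerate=True)

    def h_of(rank_rows: np.ndarray) -> np.ndarray:
        h = np.zeros(rank_rows.shape[0])
        start = 0
        for m in sizes:
            h += rank_rows[:, start:start + m].sum(axis=1) ** 2 / m
            start += m
        return (12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)) / correction

    h_obs = float(h_of(ranks[None, :])[0])
    if method == "auto":
        method = "permutation" if n_total <= 30 else "chisq"
    if method == "permutation":
        rng = np.random.default_rng(_MC_SEED)
        count = 0
        done = 0
        while done < _MC_PERMUTATIONS:
            chunk = min(50_000, _MC_PERMUTATIONS - done)
            order = np.argsort(rng.random((chunk, n_total)), axis=1)
            count += int(np.sum(h_of(ranks[order]) >= h_obs - 1e-12))
            done += chunk
        p = count / _MC_PERMUTATIONS
        return TestResult("kruskal-wallis", h_obs, p, "permutation", n_total,
                          df=len(groups) - 1, ties=ties)
    p = float(chi2.sf(h_obs, len(groups) - 1))
    return TestResult("kruskal-wallis", h_obs, p, "approximate", n_total,
                      df=len(groups) - 1, ties=ties)


# ---------------------------------------------------------------------------
# Summaries (Tukey box-and-whisker numbers)
# ---------------------------------------------------------------------------

def summarize(frame: pd.DataFrame, value: str, by) -> list[SummaryRow]:
    """Median, IQR (type-7 linear-interpolation quartiles) and Tukey whiskers.

    Whiskers extend to the most extreme data point within 1.5 IQR of the
    box. Empty groups are omitted with a log entry.
    """
    if value not in frame.columns:
        raise ValueError(f"no column {value!r}")
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    for key, sub in frame.groupby(by, sort=True, dropna=False):
        x = sub[value].dropna().to_numpy()
        if len(x) == 0:
            log.warning("empty group %s for %s; omitted", key, value)
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])   # type-7 interpolation
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        key = key if isinstance(key, tuple) else (key,)
        rows.append(SummaryRow(
            group=dict(zip(by, key)), n=len(x), median=float(med),
            q1=float(q1), q3=float(q3), iqr=float(iqr),
            whisker_low=float(lo), whisker_high=float(hi),
        ))
    return rows


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------

_SEGMENT_METRICS = ("d_l_vest", "d_l_ling", "d_angle_prox", "d_angle_dist")


@dataclass
class StudyResult:
    fibulae: pd.DataFrame
    segments: pd.DataFrame
    planes: pd.DataFrame
    tests: dict
    summaries: pd.DataFrame
    failures: list = field(default_factory=list)


def _paired_matrix(seg: pd.DataFrame, factor: str, metric: str) -> np.ndarray | None:
    """Blocks x levels matrix pairing on all other design factors."""
    block_cols = [c for c in ("design", "height", "instrument", "replicate", "segment_id")
                  if c != factor]
    wide = seg.pivot_table(index=block_cols, columns=factor, values=metric)
    wide = wide.dropna()
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        return None
    return wide.to_numpy()


def _study_tests(segments: pd.DataFrame, fibulae: pd.DataFrame,
                 design: StudyDesign) -> dict:
    tests: dict = {}
    for factor, label in (("design", "slot_design"), ("height", "guide_height")):
        if len(getattr(design, factor + "s")) < 2:
            continue
        tests[label] = {}
        for metric in _SEGMENT_METRICS:
            m = _paired_matrix(segments, factor, metric)
            if m is not None:
                tests[label][metric] = friedman_test(m).to_dict()
    if len(design.instruments) == 2:
        tests["instrument"] = {}
        for metric in _SEGMENT_METRICS:
            m = _paired_matrix(segments, "instrument", metric)
            if m is not None:
                d = m[:, 0] - m[:, 1]
                tests["instrument"][metric] = wilcoxon_signed_rank(d).to_dict()
    tests["per_segment"] = {}
    for metric in _SEGMENT_METRICS:
        groups = [g[metric].to_numpy() for _, g in segments.groupby("segment_id")]
        if len(groups) >= 2:
            tests["per_segment"][metric] = kruskal_wallis(groups).to_dict()
    if "delta_u" in fibulae.columns and len(design.designs) >= 2 and len(fibulae):
        groups = [g["delta_u"].to_numpy() for _, g in fibulae.groupby("design")]
        tests["u_distance"] = {"delta_u": kruskal_wallis(groups).to_dict()}
    return tests


def run_study(
    design: StudyDesign,
    master_seed: int = 0,
    output_dir=None,
    with_reconstruction: bool = True,
    detect_faces: bool = False,
    export_heatmaps: bool = False,
    icp_subsample: int = 2000,
    icp_max_iterations: int = 100,
    icp_tol: float = 1e-6,
) -> StudyResult:
    """Execute the whole virtual study and its statistical analysis.

    For every factorial cell and replicate: generate the fibula plan,
    perturb the cut planes under that cell's model, rebuild the executed
    segments, fit the osteotomy planes (from ground-truth cut-face
    labels, or by detection with ``detect_faces=True``), measure the
    per-segment deviations, chain-assemble the neomandible, best-fit
    align it to the plan and measure U-distance and heat-map deviation.
    Fully reproducible from ``master_seed``; failed fibulae are logged,
    skipped and counted.
    """
    params = design.fibula
    plan = make_plan(params, design.segment_lengths, design.wedge_angles)
    planned_pairs = [(sp.proximal_plane, sp.distal_plane) for sp in plan]
    planned_segments = build_segments(params, planned_pairs)
    planned_assembly = recon.assemble_neomandible(
        [s.mesh for s in planned_segments], planned_pairs, plan)
    lateral_axis = recon.lateral_axis_of_plan(plan)

    seg_rows, plane_rows, fib_rows, failures = [], [], [], []
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for cell_idx, dsg, height, instrument in design.cells():
        guide = design.guide_for(dsg, height, instrument)
        model = design.perturbation_for(dsg, height, instrument)
        for rep in range(1, design.replicates + 1):
            fib_id = f"{dsg}_h{height:g}_{instrument}_r{rep}"
            key = dict(design=dsg, height=height, instrument=instrument,
                       replicate=rep, fibula=fib_id)
            try:
                seq = design.fibula_seed(master_seed, cell_idx, rep)
                child_perturb, child_icp = seq.spawn(2)
                executed = perturb_plan(plan, model, guide, seed=child_perturb)
                segs = build_segments(params, executed)
                fitted_pairs = []
                for sm, sp in zip(segs, plan):
                    if detect_faces:
                        faces = detect_cut_faces(sm.mesh)
                    else:
                        faces = cut_faces_from_labels(sm.mesh, sm.labels)
                    prox = next(f for f in faces if f.role == "proximal")
                    dist = next(f for f in faces if f.role == "distal")
                    fitted_pairs.append((prox.fitted, dist.fitted))
                    meas = measure_segment(faces, sp)
                    seg_rows.append({**key, "segment_id": sp.segment_id,
                                     **{k: getattr(meas, k) for k in (
                                         "l_vest", "l_ling", "l_max", "l_min",
                                         "angle_prox", "angle_dist",
                                         "d_l_vest", "d_l_ling",
                                         "d_angle_prox", "d_angle_dist")}})
                    for role, fitted, planned_plane, fit_rms in (
                        ("proximal", prox.fitted, sp.proximal_plane, prox.fit_rms),
                        ("distal", dist.fitted, sp.distal_plane, dist.fit_rms),
                    ):
                        plane_rows.append({
                            **key, "segment_id": sp.segment_id, "role": role,
                            "angle_dev_deg": plane_angle(fitted, planned_plane),
                            "offset_mm": float(planned_plane.signed_distance(fitted.point)),
                            "fit_rms_mm": fit_rms,
                        })
                fib_row = dict(key)
                if with_reconstruction:
                    assembly = recon.assemble_neomandible(
                        [s.mesh for s in segs], fitted_pairs, plan)
                    rr = recon.reconstruct(
                        assembly, planned_assembly, lateral_axis,
                        subsample=icp_subsample,
                        max_iterations=icp_max_iterations,
                        tol=icp_tol,
                        seed=int(child_icp.generate_state(1)[0] % (2 ** 31)),
                    )
                    fib_row.update(
                        u_planned=rr.u_planned,
                        u_executed=rr.u_executed,
                        delta_u=rr.delta_u,
                        heat_mean=rr.heat_summary["mean"],
                        heat_rms=rr.heat_summary["rms"],
                        heat_p95=rr.heat_summary["p95"],
                        heat_max=rr.heat_summary["max"],
                        icp_rms=rr.icp.rms,
                        icp_converged=rr.icp.converged,
                    )
                    if export_heatmaps and out is not None:
                        write_ply_scalar(rr.heat, out / f"heat_{fib_id}.ply")
                fib_rows.append(fib_row)
            except OsteoguideError as exc:
                log.error("fibula %s failed: %s", fib_id, exc)
                failures.append({**key, "error": str(exc)})

    segments = pd.DataFrame(seg_rows)
    planes = pd.DataFrame(plane_rows)
    fibulae = pd.DataFrame(fib_rows)
    tests = _study_tests(segments, fibulae, design) if len(segments) else {}
    tests["counts"] = {
        "fibulae": len(fibulae), "segments": len(segments),
        "planes": len(planes), "failures": len(failures),
    }

    summary_rows = []
    for metric in _SEGMENT_METRICS:
        for factor in ("design", "height", "instrument", "segment_id"):
            for row in summarize(segments, metric, factor):
                summary_rows.append({"metric": metric, **row.group, "n": row.n,
                                     "median": row.median, "iqr": row.iqr,
                                     "q1": row.q1, "q3": row.q3,
                                     "whisker_low": row.whisker_low,
                                     "whisker_high": row.whisker_high})
    if "delta_u" in fibulae.columns and len(fibulae):
        for row in summarize(fibulae, "delta_u", "design"):
            summary_rows.append({"metric": "delta_u", **row.group, "n": row.n,
                                 "median": row.median, "iqr": row.iqr,
                                 "q1": row.q1, "q3": row.q3,
                                 "whisker_low": row.whisker_low,
                                 "whisker_high": row.whisker_high})
    summaries = pd.DataFrame(summary_rows)

    if out is not None:
        segments.to_csv(out / "segments.csv", index=False)
        planes.to_csv(out / "planes.csv", index=False)
        fibulae.to_csv(out / "reconstruction.csv", index=False)
        summaries.to_csv(out / "summaries.csv", index=False)
        with open(out / "tests.json", "w") as fh:
            json.dump(tests, fh, indent=2, sort_keys=True)

    return StudyResult(fibulae, segments, planes, tests, summaries, failures)
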