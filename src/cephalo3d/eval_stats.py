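"""Landmarking/measure accuracy metrics and between-group statistics.

Distances are Euclidean (mm); the successful detection rate (SDR) is the
percentage of distances at or below a clinical threshold (default 2 mm;
measures use 2 mm or 2 degrees on the absolute signed error). Group
differences use the Mann-Whitney U test with Benjamini-Hochberg correction
across the per-report family of landmark comparisons; p < 0.05 is considered
significant. Cases whose error exceeds a flag threshold (default 10 mm) are
listed for manual review, never auto-excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cephalometrics import CephalometricReport
from .imaging_io import LandmarkSet

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "distance",
    "sdr",
    "measure_error",
    "mann_whitney_u",
    "benjamini_hochberg",
    "evaluate",
]


def distance(t: np.ndarray, p: np.ndarray) -> float:
    """Euclidean distance (mm) between target and predicted coordinates."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    return float(np.sqrt(((t - p) ** 2).sum()))


def sdr(distances: Sequence[float], threshold: float = 2.0) -> float:
    """Successful detection rate: percent of distances <= threshold (inclusive)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("SDR of an empty distance list is undefined")
    return float(100.0 * np.count_nonzero(d <= threshold) / d.size)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U statistic of x, p-value).

    Exact p by enumeration when max(n, m) <= 8 and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney U requires two non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def measure_error(
    reference: CephalometricReport,
    predicted: CephalometricReport,
    threshold_mm: float = 2.0,
    threshold_deg: float = 2.0,
) -> pd.DataFrame:
    """Signed per-measure errors (reference - predicted) with success flags.

    Success means |error| <= 2 (mm or degrees by measure units); measures
    unavailable in either report are excluded from success and flagged.
    """
    if set(reference.measures) != set(predicted.measures):
        raise ValueError("measure id sets differ between reports")
    rows = []
    for mid, ref in reference.measures.items():
        pred = predicted.measures[mid]
        available = ref.available and pred.available
        err = None if not available else ref.value - pred.value  # type: ignore[operator]
        thr = threshold_deg if ref.units == "degrees" else threshold_mm
        rows.append(
            {
                "measure": mid,
                "units": ref.units,
                "type": ref.type,
                "error": err,
                "available": available,
                "success": bool(err is not None and abs(err) <= thr),
            }
        )
    return pd.DataFrame(rows).set_index("measure")


@dataclass(frozen=True)
class EvaluationConfig:
    sdr_threshold: float = 2.0  # mm
    flag_threshold: float = 10.0  # mm, manual-review trigger
    alpha: float = 0.05
    measure_threshold_mm: float = 2.0
    measure_threshold_deg: float = 2.0


@dataclass
class EvaluationReport:
    """Per-landmark and per-group accuracy tables plus review and miss lists."""

    landmark_table: pd.DataFrame
    group_table: pd.DataFrame
    review: pd.DataFrame
    misses: pd.DataFrame
    measure_table: pd.DataFrame | None
    config: EvaluationConfig
    pooled_p: float | None = None
    pooled_p_groups: tuple[str, ...] = field(default_factory=tuple)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.landmark_table.to_csv(out / "landmarks.csv")
        self.group_table.to_csv(out / "groups.csv")
        self.review.to_csv(out / "review.csv", index=False)
        self.misses.to_csv(out / "misses.csv", index=False)
        if self.measure_table is not None:
            self.measure_table.to_csv(out / "measures.csv")
        summary = {
            "pooled_p": self.pooled_p,
            "pooled_p_groups": list(self.pooled_p_groups),
            "config": self.config.__dict__,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))


def _mean_sd_sdr(dists: list[float], threshold: float) -> tuple[float, float, float]:
    arr = np.asarray(dists, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, sdr(arr, threshold)


def evaluate(
    predictions: Mapping[str, LandmarkSet],
    references: Mapping[str, LandmarkSet],
    metadata: Mapping[str, str] | pd.DataFrame | None = None,
    config: EvaluationConfig = EvaluationConfig(),
    reference_reports: Mapping[str, CephalometricReport] | None = None,
    predicted_reports: Mapping[str, CephalometricReport] | None = None,
) -> EvaluationReport:
    """Aggregate landmark distances, SDRs and group statistics across cases.

    ``metadata`` maps case id -> group label (or a DataFrame with ``case_id``
    and ``cohort`` columns). With exactly two groups, each landmark observed
    in both groups gets a Mann-Whitney U p-value, BH-corrected across the
    landmark family, plus one pooled comparison over all distances. Pairs
    with either landmark absent are excluded from distances and counted as
    misses. Optional per-case cephalometric report pairs are aggregated into
    a measure error table.
    """
    if set(predictions) != set(references):
        only_p = sorted(set(predictions) - set(references))
        only_r = sorted(set(references) - set(predictions))
        raise ValueError(f"case id mismatch: prediction-only {only_p}, reference-only {only_r}")
    if isinstance(metadata, pd.DataFrame):
        metadata = dict(zip(metadata["case_id"].astype(str), metadata["cohort"].astype(str)))
    groups = {cid: (metadata.get(cid, "all") if metadata else "all") for cid in references}
    group_names = tuple(sorted(set(groups.values())))

    schema_ids = next(iter(references.values())).schema_ids
    per_lm: dict[str, dict[str, list[float]]] = {
        lid: {g: [] for g in group_names} for lid in schema_ids
    }
    review_rows, miss_rows = [], []
    for cid in sorted(references):
        ref, pred, g = references[cid], predictions[cid], groups[cid]
        for lid in ref.present_ids():
            p = pred.get(lid)
            if p is None:
                miss_rows.append({"case_id": cid, "landmark": lid})
                continue
            d = distance(ref.get(lid), p)
            per_lm[lid][g].append(d)
            if d > config.flag_threshold:
                review_rows.append({"case_id": cid, "landmark": lid, "distance_mm": d})

    two_groups = len(group_names) == 2
    lm_rows, raw_p, p_index = [], [], []
    for lid in schema_ids:
        pooled = [d for g in group_names for d in per_lm[lid][g]]
        if not pooled:
            continue
        mean, sd, rate = _mean_sd_sdr(pooled, config.sdr_threshold)
        row: dict[str, object] = {
            "landmark": lid, "n": len(pooled),
            "mean_mm": mean, "sd_mm": sd, "sdr_pct": rate,
        }
        for g in group_names:
            dg = per_lm[lid][g]
            if dg:
                m, s, r = _mean_sd_sdr(dg, config.sdr_threshold)
                row[f"mean_mm_{g}"], row[f"sd_mm_{g}"], row[f"sdr_pct_{g}"] = m, s, r
                row[f"n_{g}"] = len(dg)
            else:
                row[f"mean_mm_{g}"] = row[f"sd_mm_{g}"] = row[f"sdr_pct_{g}"] = np.nan
                row[f"n_{g}"] = 0
        if two_groups:
            a, b = (per_lm[lid][g] for g in group_names)
            if a and b:
                _, p = mann_whitney_u(a, b)
                raw_p.append(p)
                p_index.append(lid)
        lm_rows.append(row)
    landmark_table = pd.DataFrame(lm_rows).set_index("landmark") if lm_rows else pd.DataFrame()
    if two_groups and raw_p:
        adj = benjamini_hochberg(raw_p)
        landmark_table["p_value"] = pd.Series(dict(zip(p_index, raw_p)))
        landmark_table["p_adj"] = pd.Series(dict(zip(p_index, adj)))
        landmark_table["significant"] = landmark_table["p_adj"] < config.alpha

    group_rows = []
    pooled_by_group = {
        g: [d for lid in schema_ids for d in per_lm[lid][g]] for g in group_names
    }
    for g in group_names:
        dg = pooled_by_group[g]
        if dg:
            m, s, r = _mean_sd_sdr(dg, config.sdr_threshold)
            group_rows.append({"group": g, "n": len(dg), "mean_mm": m, "sd_mm": s, "sdr_pct": r})
        else:
            group_rows.append({"group": g, "n": 0, "mean_mm": np.nan, "sd_mm": np.nan,
                               "sdr_pct": np.nan})
    group_table = pd.DataFrame(group_rows).set_index("group")
    pooled_p = None
    if two_groups and all(pooled_by_group[g] for g in group_names):
        _, pooled_p = mann_whitney_u(*(pooled_by_group[g] for g in group_names))

    measure_table = None
    if reference_reports is not None and predicted_reports is not None:
        mrows = []
        for cid in sorted(reference_reports):
            df = measure_error(
                reference_reports[cid], predicted_reports[cid],
                config.measure_threshold_mm, config.measure_threshold_deg,
            )
            df = df.reset_index()
            df["case_id"] = cid
            df["group"] = groups.get(cid, "all")
            mrows.append(df)
        all_m = pd.concat(mrows, ignore_index=True)
        avail = all_m[all_m["available"]]
        agg = avail.groupby("measure").agg(
            n=("error", "size"),
            mean_error=("error", "mean"),
            sd_error=("error", lambda e: e.std(ddof=1) if len(e) > 1 else 0.0),
            sdr_pct=("success", lambda s: 100.0 * s.mean()),
            units=("units", "first"),
            type=("type", "first"),
        )
        agg["n_unavailable"] = (
            all_m[~all_m["available"]].groupby("measure").size().reindex(agg.index, fill_value=0)
        )
        measure_table = agg

    return EvaluationReport(
        landmark_table=landmark_table,
        group_table=group_table,
        review=pd.DataFrame(review_rows, columns=["case_id", "landmark", "distance_mm"]),
        misses=pd.DataFrame(miss_rows, columns=["case_id", "landmark"]),
        measure_table=measure_table,
        config=config,
        pooled_p=pooled_p,
        pooled_p_groups=group_names if two_groups else (),
    )
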