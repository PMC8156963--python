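"""Suppression scoring from replicated colony sizes.

Stages, in the order the pipeline runs them:

1. plate-median normalization of raw colony sizes;
2. per-cell technical-replicate filtering and summary (mean and squared
   standard error of log2 sizes);
3. linear-regression batch correction of the second biological replicate
   onto the first;
4. Gaussian posterior combination of biological replicates: with
   between-replicate variance v = (m1−m2)²/2 and precisions
   p_i = 1/(v_i + v), the combined fitness is
   N(w1·m1 + w2·m2, 1/(p1+p2)) with w_i = p_i/(p1+p2) — the less noisy
   replicate is trusted more;
5. filtering of queries missing in the reference cross or temperature
   insensitive (reference permissive − restrictive fitness < 0.2);
6. per-strain normalization of wild-cross restrictive fitness to the
   reference using the temperature-insensitive queries;
7. suppression scoring: score = adjusted wild − reference restrictive
   fitness, sd adds in quadrature, z = score/sd, called when score ≥ 0.75
   (a 2^0.75 = 1.68-fold growth improvement) and z ≥ 4.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ScreenTable

logger = logging.getLogger("supmap.screen")


@dataclass
class ScoringThresholds:
    score_threshold: float = 0.75
    z_threshold: float = 4.5
    ts_filter_delta: float = 0.2
    tech_var_fraction: float = 0.90
    lenient_score_threshold: float = 0.5
    variance_floor_quantile: float = 0.10


@dataclass
class ReplicatePosterior:
    """Mean and squared standard error of log2 colony size over the kept
    technical replicates of one biological replicate."""

    m: float
    v: float
    n_tech: int

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.n_tech < 1:
            raise ValueError("n_tech must be >= 1")


@dataclass
class FitnessEstimate:
    query_id: str
    strain_id: str
    temperature: str
    mean: float
    sd: float
    n_bioreps: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class SuppressionScore:
    query_id: str
    strain_id: str
    score: float
    sd: float
    z: float
    p: float
    p_bonf: float
    called: bool
    n_tests: int
    degenerate_sd: bool = False


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------


def normalize_plates(table: ScreenTable) -> ScreenTable:
    """Scale each plate so its median colony size equals the batch median.

    Zeros stay zero (they scale trivially). Plates whose colonies are all
    zero or missing are flagged and excluded.
    """
    df = table.data.copy()
    nonmissing = df["colony_size"].notna()
    batch_median = df.loc[nonmissing, "colony_size"].median()
    keep = pd.Series(True, index=df.index)
    for plate, grp in df[nonmissing].groupby("plate"):
        med = grp["colony_size"].median()
        if med == 0 or np.isnan(med):
            logger.warning("plate %s has all-zero/missing colonies; excluded", plate)
            keep[df["plate"] == plate] = False
            continue
        df.loc[df["plate"] == plate, "colony_size"] *= batch_median / med
    return ScreenTable(df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Technical replicates
# ---------------------------------------------------------------------------


def filter_technical(replicates: list[float], tech_var_fraction: float = 0.90
                     ) -> list[float]:
    """Drop at most one outlying technical replicate.

    A replicate is removed when its squared deviation from the mean of the
    other replicates accounts for at least ``tech_var_fraction`` of the total
    sum of squared deviations about the cell mean, and it is the unique such
    maximum. Two-replicate cells are never filtered (their shares are equal
    by symmetry).
    """
    x = np.asarray([r for r in replicates if not np.isnan(r)], dtype=float)
    if x.size <= 1:
        return x.tolist()
    total_ss = float(np.sum((x - x.mean()) ** 2))
    if total_ss == 0.0:
        return x.tolist()
    n = x.size
    loo_dev = np.empty(n)
    for j in range(n):
        others = np.delete(x, j)
        loo_dev[j] = (x[j] - others.mean()) ** 2
    share = loo_dev / total_ss
    top = int(np.argmax(share))
    is_unique = np.sum(share == share[top]) == 1
    if share[top] >= tech_var_fraction and is_unique:
        return np.delete(x, top).tolist()
    return x.tolist()


def summarize_technical(kept: list[float], variance_floor: float = 1e-4
                        ) -> ReplicatePosterior | None:
    """Mean and squared standard error of the kept log2 sizes.

    Returns None for an empty cell. Single-replicate and zero-variance cells
    take ``variance_floor`` as v (no cell is allowed infinite precision).
    """
    x = np.asarray([r for r in kept if not np.isnan(r)], dtype=float)
    if x.size == 0:
        return None
    m = float(x.mean())
    if x.size == 1:
        return ReplicatePosterior(m, variance_floor, 1)
    v = float(x.var(ddof=1) / x.size)
    if v == 0.0:
        v = variance_floor
    return ReplicatePosterior(m, v, int(x.size))


# ---------------------------------------------------------------------------
# Biological replicates
# ---------------------------------------------------------------------------


def batch_correct(biorep2: pd.DataFrame, biorep1: pd.DataFrame,
                  min_shared: int = 10) -> pd.DataFrame:
    """Fit replicate 2 onto replicate 1 by ordinary least squares.

    Both frames are indexed by query with columns ``m`` and ``v``. The fit
    rep1_m = a + b·rep2_m over shared queries transforms rep2 means to
    a + b·m and scales variances by b². With fewer than ``min_shared``
    shared queries the correction is skipped with a warning.
    """
    shared = biorep1.index.intersection(biorep2.index)
    if len(shared) < min_shared:
        logger.warning("batch correction skipped: only %d shared queries",
                       len(shared))
        return biorep2.copy()
    slope, intercept, *_ = stats.linregress(biorep2.loc[shared, "m"],
                                            biorep1.loc[shared, "m"])
    corrected = biorep2.copy()
    corrected["m"] = intercept + slope * corrected["m"]
    corrected["v"] = corrected["v"] * slope ** 2
    return corrected


def combine_bioreps(r1: ReplicatePosterior, r2: ReplicatePosterior | None,
                    query_id: str = "", strain_id: str = "",
                    temperature: str = "") -> FitnessEstimate:
    """Gaussian posterior combination of two biological replicates.

    Biological noise is estimated from the between-replicate difference as
    v = (m1−m2)²/2; each replicate's posterior widens to v_i + v, and the
    precision-weighted average N(w1 m1 + w2 m2, 1/(p1+p2)) is returned.
    With one replicate, the technical summary passes through.
    """
    if r2 is None:
        return FitnessEstimate(query_id, strain_id, temperature,
                               r1.m, math.sqrt(r1.v), 1)
    v = (r1.m - r2.m) ** 2 / 2.0
    p1 = 1.0 / (r1.v + v)
    p2 = 1.0 / (r2.v + v)
    w1 = p1 / (p1 + p2)
    w2 = p2 / (p1 + p2)
    mean = w1 * r1.m + w2 * r2.m
    sd = math.sqrt(1.0 / (p1 + p2))
    return FitnessEstimate(query_id, strain_id, temperature, mean, sd, 2)


# ---------------------------------------------------------------------------
# Query filtering and reference normalization
# ---------------------------------------------------------------------------


def filter_queries(estimates: pd.DataFrame, thresholds: ScoringThresholds,
                   reference_strain: str = "REF"
                   ) -> tuple[set[str], set[str], pd.DataFrame]:
    """Drop unusable and temperature-insensitive queries.

    ``estimates`` has one row per (query_id, strain_id, temperature) with a
    ``mean`` column. Returns (retained queries, temperature-insensitive
    queries among the retained input, drop log with reasons). Insensitive
    queries — reference-cross permissive − restrictive fitness below
    ``ts_filter_delta`` — are dropped from scoring but returned for use as
    the normalization anchor set.
    """
    piv = estimates.pivot_table(index="query_id", columns=["strain_id", "temperature"],
                                values="mean", aggfunc="first")
    drops = []
    retained, insensitive = set(), set()
    for query in piv.index:
        ref_restrictive = piv.loc[query].get((reference_strain, "restrictive"), np.nan)
        ref_permissive = piv.loc[query].get((reference_strain, "permissive"), np.nan)
        wild_cols = [c for c in piv.columns
                     if c[0] != reference_strain and c[1] == "restrictive"]
        wild_present = piv.loc[query, wild_cols].notna().any() if wild_cols else False
        if np.isnan(ref_restrictive):
            drops.append((query, "missing_in_reference"))
            continue
        if not wild_present:
            drops.append((query, "missing_in_all_wild"))
            continue
        if not np.isnan(ref_permissive) and \
                (ref_permissive - ref_restrictive) < thresholds.ts_filter_delta:
            drops.append((query, "temperature_insensitive"))
            insensitive.add(query)
            continue
        retained.add(query)
    log = pd.DataFrame(drops, columns=["query_id", "reason"])
    return retained, insensitive, log


def normalize_to_reference(wild: pd.DataFrame, reference: pd.DataFrame,
                           insensitive: set[str], min_shared: int = 10
                           ) -> tuple[pd.DataFrame, float, float]:
    """Adjust one wild strain's restrictive fitnesses onto the reference scale.

    Both frames are indexed by query with columns ``mean`` and ``sd``. The
    temperature-insensitive queries anchor the fit: wild fitnesses are
    shifted so the insensitive-set medians agree, then deviations about the
    median are rescaled onto the reference scale. The scale is the
    equal-noise Deming slope (the ratio of anchor-deviation spreads, signed
    by their covariance) rather than the ordinary regression slope: both
    axes carry comparable measurement noise, and the attenuation of an
    ordinary fit would bias the adjusted fitness of every TS-sensitive
    query, which lies far below the anchor median. sds scale by |scale|.
    Returns (adjusted frame, shift, scale).
    """
    anchors = sorted(insensitive & set(wild.index) & set(reference.index))
    if len(anchors) == 0:
        logger.warning("no shared insensitive queries; wild estimates unadjusted")
        return wild.copy(), 0.0, 1.0
    med_wild = float(wild.loc[anchors, "mean"].median())
    med_ref = float(reference.loc[anchors, "mean"].median())
    dev_wild = wild.loc[anchors, "mean"].to_numpy() - med_wild
    dev_ref = reference.loc[anchors, "mean"].to_numpy() - med_ref
    if len(anchors) < min_shared or np.sum(dev_wild ** 2) == 0:
        if len(anchors) < min_shared:
            logger.warning("only %d shared insensitive queries; shift-only "
                           "normalization", len(anchors))
        scale = 1.0
    else:
        scale = float(np.sqrt(np.sum(dev_ref ** 2) / np.sum(dev_wild ** 2)))
        if np.sum(dev_wild * dev_ref) < 0:
            scale = -scale
    adjusted = wild.copy()
    adjusted["mean"] = med_ref + scale * (wild["mean"] - med_wild)
    adjusted["sd"] = wild["sd"] * abs(scale)
    shift = med_ref - med_wild
    return adjusted, shift, scale


# ---------------------------------------------------------------------------
# Suppression scoring
# ---------------------------------------------------------------------------


def suppression_score(wild: FitnessEstimate, reference: FitnessEstimate,
                      thresholds: ScoringThresholds, n_tests: int
                      ) -> SuppressionScore:
    """Adjusted restrictive-temperature fitness difference, wild − reference.

    The two posteriors are treated as independent (variances add). The
    one-sided normal p-value for suppression > 0 and its Bonferroni
    correction (×n_tests, capped at 1) are reported alongside the call.
    """
    score = wild.mean - reference.mean
    sd = math.sqrt(wild.sd ** 2 + reference.sd ** 2)
    degenerate = sd == 0.0
    if degenerate:
        z = math.inf if score > 0 else (-math.inf if score < 0 else 0.0)
        logger.warning("zero posterior sd for %s x %s", wild.query_id,
                       wild.strain_id)
    else:
        z = score / sd
    p = float(stats.norm.sf(z))
    p_bonf = min(p * n_tests, 1.0)
    called = (score >= thresholds.score_threshold) and (z >= thresholds.z_threshold)
    return SuppressionScore(wild.query_id, wild.strain_id, score, sd, z, p,
                            p_bonf, called, n_tests, degenerate)


def fold_change(score_threshold: float = 0.75) -> float:
    """Growth fold-change corresponding to a log2 suppression score."""
    return 2.0 ** score_threshold


def nominal_p(z_threshold: float = 4.5) -> float:
    """One-sided normal tail probability at the z threshold."""
    return float(stats.norm.sf(z_threshold))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def summarize_cells(table: ScreenTable, thresholds: ScoringThresholds
                    ) -> pd.DataFrame:
    """Technical filtering + summary for every (query, strain, temp, biorep).

    The single-replicate/zero-variance floor is the
    ``variance_floor_quantile`` of positive v across all cells.
    """
    df = table.data.copy()
    df = df[df["colony_size"].notna()]
    df["log2_size"] = np.log2(df["colony_size"] + 1.0)
    cells = []
    for key, grp in df.groupby(["query_id", "strain_id", "temperature",
                                "biological_rep"], sort=False):
        kept = filter_technical(grp["log2_size"].tolist(),
                                thresholds.tech_var_fraction)
        if not kept:
            continue
        x = np.asarray(kept)
        v = float(x.var(ddof=1) / x.size) if x.size > 1 else np.nan
        cells.append((*key, float(x.mean()), v, x.size))
    out = pd.DataFrame(cells, columns=["query_id", "strain_id", "temperature",
                                       "biological_rep", "m", "v", "n_tech"])
    positive = out["v"][out["v"] > 0]
    floor = float(positive.quantile(thresholds.variance_floor_quantile)) \
        if len(positive) else 1e-4
    out["v"] = out["v"].fillna(floor).clip(lower=floor)
    return out


def combine_all(cells: pd.DataFrame, batch_correction: bool = True
                ) -> pd.DataFrame:
    """Batch-correct replicate 2 and combine biological replicates.

    Cells with more than two biological replicates are combined by iterated
    pairwise combination in replicate order. Returns one row per
    (query_id, strain_id, temperature) with posterior mean and sd.
    """
    rows = []
    for (strain, temp), grp in cells.groupby(["strain_id", "temperature"],
                                             sort=False):
        reps = sorted(grp["biological_rep"].unique())
        frames = {r: grp[grp["biological_rep"] == r]
                  .set_index("query_id")[["m", "v"]] for r in reps}
        if batch_correction:
            for r in reps[1:]:
                frames[r] = batch_correct(frames[r], frames[reps[0]])
        queries = sorted(set().union(*[set(f.index) for f in frames.values()]))
        for query in queries:
            posterior: ReplicatePosterior | None = None
            for r in reps:
                if query not in frames[r].index:
                    continue
                row = frames[r].loc[query]
                nxt = ReplicatePosterior(float(row["m"]), float(row["v"]),
                                         int(grp.loc[(grp["query_id"] == query) &
                                                     (grp["biological_rep"] == r),
                                                     "n_tech"].iloc[0]))
                if posterior is None:
                    posterior = nxt
                else:
                    est = combine_bioreps(posterior, nxt)
                    posterior = ReplicatePosterior(est.mean, est.sd ** 2, 1)
            if posterior is not None:
                est = combine_bioreps(posterior, None, query, strain, temp)
                rows.append((query, strain, temp, est.mean, est.sd))
    return pd.DataFrame(rows, columns=["query_id", "strain_id", "temperature",
                                       "mean", "sd"])


def score_screen(table: ScreenTable,
                 thresholds: ScoringThresholds | None = None,
                 reference_strain: str = "REF",
                 normalize: bool = True) -> pd.DataFrame:
    """Run the full scoring pipeline on a screen table.

    Returns one row per (query, wild strain) with score, sd, z, p, p_bonf
    and the suppression call; n_tests is retained queries × wild strains.
    """
    thresholds = thresholds or ScoringThresholds()
    cells = summarize_cells(normalize_plates(table), thresholds)
    estimates = combine_all(cells)
    retained, insensitive, _drop_log = filter_queries(estimates, thresholds,
                                                      reference_strain)
    restrictive = estimates[estimates["temperature"] == "restrictive"]
    ref = restrictive[restrictive["strain_id"] == reference_strain] \
        .set_index("query_id")[["mean", "sd"]]
    wild_strains = [s for s in restrictive["strain_id"].unique()
                    if s != reference_strain]
    n_tests = max(len(retained) * len(wild_strains), 1)
    records = []
    for strain in wild_strains:
        wild = restrictive[restrictive["strain_id"] == strain] \
            .set_index("query_id")[["mean", "sd"]]
        if normalize:
            wild, _, _ = normalize_to_reference(wild, ref, insensitive)
        for query in sorted(retained & set(wild.index) & set(ref.index)):
            w = FitnessEstimate(query, strain, "restrictive",
                                float(wild.loc[query, "mean"]),
                                float(wild.loc[query, "sd"]), 1)
            r = FitnessEstimate(query, reference_strain, "restrictive",
                                float(ref.loc[query, "mean"]),
                                float(ref.loc[query, "sd"]), 1)
            s = suppression_score(w, r, thresholds, n_tests)
            records.append((query, strain, s.score, s.sd, s.z, s.p, s.p_bonf,
                            s.called))
    return pd.DataFrame(records, columns=["query_id", "strain_id", "score",
                                          "sd", "z", "p", "p_bonf", "called"])


# ---------------------------------------------------------------------------
# Random sporulation confirmation assay
# ---------------------------------------------------------------------------


def confirmation_assay(counts: pd.DataFrame, margin: float = 1.0,
                       min_colonies_analysis: int = 100,
                       min_colonies_size: int = 30) -> pd.DataFrame:
    """Confirmation statistics from single-colony counts and areas.

    ``counts`` has one row per (cross, temperature) with columns
    ``cross`` ("wild"/"reference" per pair id), ``pair_id``, ``temperature``,
    ``n_colonies`` and ``mean_area``. The count statistic is
    log2(count34/count26) in the wild cross minus the same ratio in the
    reference cross; the area statistic is analogous. Images with fewer than
    100 colonies at 26°C are excluded from the analysis, and those with
    fewer than 30 colonies from size determination. Zero counts at 34°C are
    continuity-corrected to 0.5 and flagged.
    """
    results = []
    for pair_id, grp in counts.groupby("pair_id"):
        rec: dict = {"pair_id": pair_id, "excluded": False,
                     "zero_corrected": False}
        vals: dict[tuple[str, str], dict] = {
            (row["cross"], row["temperature"]): row for _, row in grp.iterrows()}
        try:
            w26, w34 = vals[("wild", "permissive")], vals[("wild", "restrictive")]
            r26, r34 = vals[("reference", "permissive")], vals[("reference", "restrictive")]
        except KeyError:
            rec["excluded"] = True
            results.append(rec)
            continue
        if w26["n_colonies"] < min_colonies_analysis or \
                r26["n_colonies"] < min_colonies_analysis:
            rec["excluded"] = True
            results.append(rec)
            continue

        def count_of(row: dict) -> float:
            n = row["n_colonies"]
            if n == 0:
                rec["zero_corrected"] = True
                return 0.5
            return float(n)

        count_stat = (math.log2(count_of(w34) / count_of(w26))
                      - math.log2(count_of(r34) / count_of(r26)))
        rec["count_statistic"] = count_stat
        size_ok = all(v["n_colonies"] >= min_colonies_size
                      for v in (w26, w34, r26, r34))
        if size_ok and all(v["mean_area"] > 0 for v in (w26, w34, r26, r34)):
            rec["area_statistic"] = (math.log2(w34["mean_area"] / w26["mean_area"])
                                     - math.log2(r34["mean_area"] / r26["mean_area"]))
        else:
            rec["area_statistic"] = np.nan
        rec["confirmed"] = bool(count_stat >= margin or
                                (not np.isnan(rec["area_statistic"])
                                 and rec["area_statistic"] >= margin))
        results.append(rec)
    return pd.DataFrame(results)
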