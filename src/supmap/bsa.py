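"""Bulk segregant analysis: frequency tracks, QTL calling, aneuploidy.

Wild-allele frequencies along each chromosome are latent variables observed
through binomial read counts; frequencies at nearby sites are coupled by the
recombination map. Inference runs forward–backward smoothing on a
discretized frequency grid: emissions are Binomial(depth, (1−e)·f + e·(1−f))
with a per-read mis-assignment rate e, and transitions between adjacent
sites are a Gaussian random walk whose step variance is proportional to the
recombination distance (Morgans) between them. Replicate tracks combine by
precision weighting; the restrictive − permissive difference track, masked
around the TS allele and SGA selection markers, is scanned for QTL regions
with two-threshold hysteresis at a lenient (0.12) and a strict (0.20)
frequency-change cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AlleleCountTable, QTLRegion
from .synthetic import Locus

logger = logging.getLogger("supmap.bsa")


@dataclass
class MapperParams:
    """Thresholds and model parameters of the mapping stage.

    ``af_stringent`` (0.12) seeds the broad/lenient region set and
    ``strict_delta`` (0.20) the strict set; both require |delta|/sd at least
    ``sd_stringent`` at the seed. ``af_lenient`` and ``sd_lenient`` govern
    region extension (module-defined semantics, see docs): an extension site
    must keep the seed's sign, |delta| >= peak_cutoff, and either
    |delta| >= af_lenient x the tier's seed threshold or
    |delta|/sd >= sd_lenient.
    """

    af_lenient: float = 0.8
    sd_lenient: float = 3.0
    af_stringent: float = 0.12
    sd_stringent: float = 5.0
    length_cutoff: int = 1000
    peak_cutoff: float = 0.03
    strict_delta: float = 0.20
    mask_radius: int = 30_000
    recombination_rate: float = 4e-6
    error_rate: float = 0.002
    grid_size: int = 101
    diffusion_scale: float = 1.0
    aneuploidy_high: float = 1.35
    aneuploidy_low: float = 0.65


@dataclass
class FrequencyTrack:
    """Posterior wild-allele frequency along one chromosome."""

    chrom: str
    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    temperature: str = ""
    replicate: str | int = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.positions) == len(self.mean) == len(self.sd)):
            raise ValueError("track arrays must have equal length")
        if len(self.mean) and (self.mean.min() < -1e-9 or self.mean.max() > 1 + 1e-9):
            raise ValueError("frequencies must lie in [0, 1]")


@dataclass
class DeltaTrack:
    """Wild-allele frequency change (restrictive − permissive)."""

    chrom: str
    positions: np.ndarray
    delta: np.ndarray
    sd: np.ndarray
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.delta = np.asarray(self.delta, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.masked is None:
            self.masked = np.zeros(len(self.positions), dtype=bool)
        self.masked = np.asarray(self.masked, dtype=bool)


# ---------------------------------------------------------------------------
# Track estimation
# ---------------------------------------------------------------------------


def _transition_matrices(positions: np.ndarray, params: MapperParams,
                         grid: np.ndarray) -> list[np.ndarray]:
    """Row-normalized Gaussian random-walk kernels between adjacent sites."""
    mats = []
    for d_bp in np.diff(positions):
        var = params.diffusion_scale * params.recombination_rate * float(d_bp)
        sd = max(np.sqrt(var), 1e-6)
        kernel = np.exp(-0.5 * ((grid[None, :] - grid[:, None]) / sd) ** 2)
        mats.append(kernel / kernel.sum(axis=1, keepdims=True))
    return mats


def _emission_matrix(ref: np.ndarray, alt: np.ndarray, params: MapperParams,
                     grid: np.ndarray) -> np.ndarray:
    """Likelihood of each site's counts at every grid frequency."""
    depth = ref + alt
    p_obs = (1.0 - params.error_rate) * grid + params.error_rate * (1.0 - grid)
    p_obs = np.clip(p_obs, 1e-12, 1.0 - 1e-12)
    return stats.binom.pmf(alt[:, None], depth[:, None], p_obs[None, :])


def estimate_track(positions: np.ndarray, ref: np.ndarray, alt: np.ndarray,
                   chrom: str, params: MapperParams | None = None,
                   temperature: str = "", replicate: str | int = ""
                   ) -> FrequencyTrack:
    """Posterior mean/sd of the latent wild-allele frequency at each site.

    Zero-depth sites contribute a flat emission and take the smoothed prior.
    The grid has ``params.grid_size`` uniformly spaced levels on [0, 1].
    """
    params = params or MapperParams()
    positions = np.asarray(positions, dtype=int)
    n = len(positions)
    if n == 0:
        return FrequencyTrack(chrom, positions, np.array([]), np.array([]),
                              temperature, replicate)
    grid = np.linspace(0.0, 1.0, params.grid_size)
    emissions = _emission_matrix(np.asarray(ref, dtype=int),
                                 np.asarray(alt, dtype=int), params, grid)
    trans = _transition_matrices(positions, params, grid)

    # forward-backward with per-site normalization
    g = params.grid_size
    fwd = np.empty((n, g))
    alpha = emissions[0] / g
    fwd[0] = alpha / alpha.sum()
    for i in range(1, n):
        alpha = (fwd[i - 1] @ trans[i - 1]) * emissions[i]
        fwd[i] = alpha / alpha.sum()
    bwd = np.empty((n, g))
    bwd[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta = trans[i] @ (bwd[i + 1] * emissions[i + 1])
        bwd[i] = beta / beta.sum()
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ grid
    second = post @ grid ** 2
    sd = np.sqrt(np.maximum(second - mean ** 2, 0.0))
    return FrequencyTrack(chrom, positions, mean, sd, temperature, replicate)


def estimate_tracks(counts: AlleleCountTable, sample_id: str,
                    params: MapperParams | None = None) -> list[FrequencyTrack]:
    """One track per chromosome for a sample of an allele-count table."""
    params = params or MapperParams()
    meta = counts.metadata.get(sample_id, {})
    tracks = []
    sample = counts.sample(sample_id)
    for chrom, grp in sample.groupby("chrom", sort=False):
        tracks.append(estimate_track(
            grp["pos"].to_numpy(), grp["ref_count"].to_numpy(),
            grp["alt_count"].to_numpy(), str(chrom), params,
            temperature=meta.get("temperature", ""),
            replicate=meta.get("replicate", "")))
    return tracks


def combine_tracks(tracks: list[FrequencyTrack]) -> FrequencyTrack:
    """Precision-weighted Gaussian combination of replicate tracks
    (precision = 1/sd² per site), clipped to [0, 1]."""
    if not tracks:
        raise ValueError("no tracks to combine")
    first = tracks[0]
    for t in tracks[1:]:
        if t.chrom != first.chrom or not np.array_equal(t.positions,
                                                        first.positions):
            raise ValueError("tracks are on different site grids")
    prec = np.stack([1.0 / np.maximum(t.sd, 1e-9) ** 2 for t in tracks])
    means = np.stack([t.mean for t in tracks])
    total = prec.sum(axis=0)
    mean = np.clip((prec * means).sum(axis=0) / total, 0.0, 1.0)
    sd = np.sqrt(1.0 / total)
    return FrequencyTrack(first.chrom, first.positions, mean, sd,
                          temperature=first.temperature, replicate="combined")


def delta_track(restrictive: FrequencyTrack, permissive: FrequencyTrack
                ) -> DeltaTrack:
    """Wild-allele frequency change: restrictive mean − permissive mean,
    with sds added in quadrature."""
    if restrictive.chrom != permissive.chrom or \
            not np.array_equal(restrictive.positions, permissive.positions):
        raise ValueError("tracks are on different site grids")
    return DeltaTrack(restrictive.chrom, restrictive.positions,
                      restrictive.mean - permissive.mean,
                      np.sqrt(restrictive.sd ** 2 + permissive.sd ** 2))


def mask_linked(delta: DeltaTrack, ts_locus: Locus | None,
                marker_loci: list[Locus] = (), mask_radius: int = 30_000
                ) -> DeltaTrack:
    """Flag sites within ``mask_radius`` of the TS allele or any SGA
    selection marker; flagged sites cannot seed or extend QTL regions."""
    masked = delta.masked.copy()
    loci = ([ts_locus] if ts_locus is not None else []) + list(marker_loci)
    for locus in loci:
        if locus.chrom != delta.chrom:
            continue
        masked |= np.abs(delta.positions - locus.pos) <= mask_radius
    return DeltaTrack(delta.chrom, delta.positions, delta.delta, delta.sd,
                      masked)


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------


def _call_tier(delta: DeltaTrack, params: MapperParams, seed_threshold: float,
               tier: str, cross_id: str) -> list[QTLRegion]:
    d = delta.delta
    sd = np.maximum(delta.sd, 1e-12)
    z = np.abs(d) / sd
    eligible = ~delta.masked
    seeds = eligible & (np.abs(d) >= seed_threshold) & (z >= params.sd_stringent)
    extend_ok = eligible & (np.abs(d) >= params.peak_cutoff) & (
        (np.abs(d) >= params.af_lenient * seed_threshold)
        | (z >= params.sd_lenient))

    n = len(d)
    visited = np.zeros(n, dtype=bool)
    intervals: list[tuple[int, int, int]] = []  # (start_idx, end_idx, sign)
    for i in np.flatnonzero(seeds):
        if visited[i]:
            continue
        sign = 1 if d[i] > 0 else -1
        lo = i
        while lo - 1 >= 0 and extend_ok[lo - 1] and np.sign(d[lo - 1]) == sign:
            lo -= 1
        hi = i
        while hi + 1 < n and extend_ok[hi + 1] and np.sign(d[hi + 1]) == sign:
            hi += 1
        visited[lo:hi + 1] = True
        intervals.append((lo, hi, sign))

    # merge same-sign intervals separated by less than length_cutoff
    intervals.sort()
    merged: list[tuple[int, int, int]] = []
    for lo, hi, sign in intervals:
        if merged and sign == merged[-1][2] and \
                delta.positions[lo] - delta.positions[merged[-1][1]] < \
                params.length_cutoff:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]), sign)
        else:
            merged.append((lo, hi, sign))

    regions = []
    for lo, hi, sign in merged:
        start = int(delta.positions[lo])
        end = int(delta.positions[hi])
        if end - start + 1 < params.length_cutoff:
            continue
        idx = np.arange(lo, hi + 1)
        idx = idx[~delta.masked[idx]]
        peak_i = idx[np.argmax(np.abs(d[idx]))]
        regions.append(QTLRegion(
            chrom=delta.chrom, start=start, end=end,
            peak_pos=int(delta.positions[peak_i]),
            delta_peak=float(d[peak_i]),
            direction="wild_beneficial" if sign > 0 else "reference_beneficial",
            tier=tier, cross_id=cross_id))
    return regions


def call_qtl(delta: DeltaTrack, params: MapperParams | None = None,
             cross_id: str = "cross") -> list[QTLRegion]:
    """Call QTL regions on one masked delta track.

    Two tiers are reported: ``lenient`` regions seeded at
    |delta| ≥ af_stringent (0.12) and ``stringent`` regions seeded at
    |delta| ≥ strict_delta (0.20); both require |delta|/sd ≥ sd_stringent at
    the seed and a region length of at least ``length_cutoff``.
    """
    params = params or MapperParams()
    regions = _call_tier(delta, params, params.strict_delta, "stringent",
                         cross_id)
    regions += _call_tier(delta, params, params.af_stringent, "lenient",
                          cross_id)
    return regions


# ---------------------------------------------------------------------------
# Aneuploidy detection
# ---------------------------------------------------------------------------


def detect_aneuploidy(sample: pd.DataFrame, params: MapperParams | None = None
                      ) -> dict[str, dict]:
    """Per-chromosome relative read depth for one sample.

    Ratio = median site depth on the chromosome / genome-wide median site
    depth; flagged aneuploid outside [aneuploidy_low, aneuploidy_high]. The
    flag is withheld (None) for chromosomes with fewer than 10 sites.
    """
    params = params or MapperParams()
    depth = sample["ref_count"] + sample["alt_count"]
    genome_median = float(depth.median())
    out: dict[str, dict] = {}
    for chrom, grp in sample.groupby("chrom", sort=False):
        d = grp["ref_count"] + grp["alt_count"]
        ratio = float(d.median()) / genome_median if genome_median > 0 else np.nan
        if len(grp) < 10:
            flag = None
        else:
            flag = bool(ratio >= params.aneuploidy_high
                        or ratio <= params.aneuploidy_low)
        out[str(chrom)] = {"ratio": ratio, "n_sites": int(len(grp)),
                           "aneuploid": flag}
    return out


# ---------------------------------------------------------------------------
# Full mapping pipeline
# ---------------------------------------------------------------------------


def map_bsa(counts: AlleleCountTable, ts_locus: Locus | None = None,
            marker_loci: list[Locus] = (),
            params: MapperParams | None = None,
            cross_id: str = "cross") -> dict:
    """Run the mapping stage for one cross.

    Estimates per-sample frequency tracks, combines replicates within each
    temperature, forms the masked delta track per chromosome, calls QTL
    regions and flags aneuploidies. Sample metadata must provide
    ``temperature`` and ``replicate`` for each sample of the cross.
    """
    params = params or MapperParams()
    by_temp: dict[str, list[list[FrequencyTrack]]] = {}
    aneuploidy = {}
    for sample_id in counts.sample_ids():
        meta = counts.metadata.get(sample_id, {})
        if meta.get("cross_id", cross_id) != cross_id:
            continue
        tracks = estimate_tracks(counts, sample_id, params)
        by_temp.setdefault(meta.get("temperature", ""), []).append(tracks)
        aneuploidy[sample_id] = detect_aneuploidy(counts.sample(sample_id),
                                                  params)
    combined: dict[str, dict[str, FrequencyTrack]] = {}
    for temp, replicate_tracks in by_temp.items():
        per_chrom: dict[str, list[FrequencyTrack]] = {}
        for tracks in replicate_tracks:
            for t in tracks:
                per_chrom.setdefault(t.chrom, []).append(t)
        combined[temp] = {c: combine_tracks(ts) for c, ts in per_chrom.items()}
    regions: list[QTLRegion] = []
    deltas: list[DeltaTrack] = []
    if "restrictive" in combined and "permissive" in combined:
        for chrom in combined["restrictive"]:
            dt = delta_track(combined["restrictive"][chrom],
                             combined["permissive"][chrom])
            dt = mask_linked(dt, ts_locus, marker_loci, params.mask_radius)
            deltas.append(dt)
            regions.extend(call_qtl(dt, params, cross_id))
    return {"tracks": combined, "deltas": deltas, "regions": regions,
            "aneuploidy": aneuploidy}
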