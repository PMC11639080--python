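"""Fold and score sampled windows; aggregate and correlate per region.

Produces the per-window profile (MFE, |MFE|, ensemble free energy,
ensemble diversity, GC fraction, dyad density), per-(region,
chromosome) and per-region aggregates, Pearson correlations of |MFE|
against GC content / dyad density, the correlation of per-chromosome
|MFE| with missegregation probabilities, and the window-length
sensitivity report (is the region ranking by mean MFE stable across
500 / 1,000 / 4,000 nt windows?).

|MFE| is used so that larger positive values mean more stable
structures.  Correlations default to per-chromosome pairing: the mean
|MFE| of a chromosome's windows against that chromosome's region-wide
GC / dyad density when available (window means otherwise); per-window
pairing is available as an option.  Standard deviations are the sample
(n-1) form.  No multiple-testing correction is applied; n is reported
alongside every r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fold import FoldOptions, fold_mfe, partition_function
from .motifs import PalindromeParams, dyad_density, find_palindromes
from .params import EnergyParameters
from .sequence import NucleotideSequence

__all__ = [
    "gc_content",
    "profile_windows",
    "aggregate_profile",
    "pearson",
    "correlate_features",
    "correlate_missegregation",
    "length_sensitivity",
    "UndefinedCorrelationError",
]

log = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "chrom", "region_label", "window_id", "window_length", "mfe", "abs_mfe",
    "ensemble_free_energy", "ensemble_diversity", "gc_fraction", "dyad_density",
]


class UndefinedCorrelationError(ValueError):
    """A correlation was requested on a zero-variance or too-short vector."""


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N excluded from the denominator.

    All-N sequences return 0.0 with a logged flag.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        log.warning("gc_content: no ACGT bases present; returning 0")
        return 0.0
    return gc / acgt


def profile_windows(
    windows: list[NucleotideSequence],
    params: EnergyParameters,
    opts: FoldOptions = FoldOptions(),
    palindrome_params: PalindromeParams = PalindromeParams(),
    ensemble: bool = True,
    collect_structures: list | None = None,
) -> pd.DataFrame:
    """One row per window with all five measurements.

    ``ensemble=False`` skips the partition function (ensemble columns
    become NaN), which is how large MFE-ranking runs stay fast.  Pass a
    list as ``collect_structures`` to also receive (window id,
    dot-bracket, mfe) triples.
    """
    rows = []
    for w in windows:
        try:
            if ensemble:
                res = partition_function(w.seq, params, opts)
                efe, div = res.ensemble_free_energy, res.ensemble_diversity
            else:
                res = fold_mfe(w.seq, params, opts)
                efe = div = np.nan
            if collect_structures is not None:
                collect_structures.append((w.id, res.dotbracket(), res.mfe))
            hits = find_palindromes(w.seq, palindrome_params)
            rows.append({
                "chrom": w.chrom,
                "region_label": w.region_label,
                "window_id": w.id,
                "window_length": len(w),
                "mfe": res.mfe,
                "abs_mfe": abs(res.mfe),
                "ensemble_free_energy": efe,
                "ensemble_diversity": div,
                "gc_fraction": gc_content(w.seq),
                "dyad_density": dyad_density(len(w), hits),
            })
        except Exception as exc:
            raise RuntimeError(f"profiling failed for window {w.id}") from exc
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def aggregate_profile(profile: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-region-and-chromosome, per-region) mean/sd aggregates."""
    metrics = ["mfe", "abs_mfe", "ensemble_free_energy", "ensemble_diversity",
               "gc_fraction", "dyad_density"]
    by_chrom = (
        profile.groupby(["region_label", "chrom"])[metrics]
        .agg(["mean", "std", "count"])
    )
    by_region = profile.groupby("region_label")[metrics].agg(["mean", "std", "count"])
    return by_chrom, by_region


def pearson(x, y) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise UndefinedCorrelationError("zero variance on one side")
    return float(sps.pearsonr(x, y).statistic)


def correlate_features(
    profile: pd.DataFrame,
    region_stats: pd.DataFrame | None = None,
    per_window: bool = False,
) -> pd.DataFrame:
    """Per region: r(|MFE|, dyad density) and r(|MFE|, GC fraction).

    Default pairing is per chromosome: the chromosome's mean window
    |MFE| against its region-wide dyad density / GC when
    ``region_stats`` (columns chrom, region_label, gc_fraction,
    dyad_density) is given, else against its mean window values.
    ``per_window=True`` pairs raw windows instead.
    """
    out = []
    for region, sub in profile.groupby("region_label"):
        if per_window:
            paired = sub[["abs_mfe", "dyad_density", "gc_fraction"]]
        else:
            paired = (
                sub.groupby("chrom")[["abs_mfe", "dyad_density", "gc_fraction"]]
                .mean()
                .reset_index()
            )
            if region_stats is not None:
                rs = region_stats[region_stats.region_label == region]
                paired = paired[["chrom", "abs_mfe"]].merge(
                    rs[["chrom", "gc_fraction", "dyad_density"]], on="chrom"
                )
        if len(paired) < 3:
            raise UndefinedCorrelationError(
                f"region {region}: need >= 3 {'windows' if per_window else 'chromosomes'}"
            )
        out.append({
            "region_label": region,
            "n": len(paired),
            "r_abs_mfe_dyad": pearson(paired.abs_mfe, paired.dyad_density),
            "r_abs_mfe_gc": pearson(paired.abs_mfe, paired.gc_fraction),
        })
    return pd.DataFrame(out)


def correlate_missegregation(
    per_chrom_abs_mfe: pd.Series | dict[str, float],
    table: pd.Series | dict[str, float],
) -> tuple[float, int]:
    """r between per-chromosome |MFE| and missegregation probability.

    Chromosomes missing from either side are dropped and logged;
    returns (r, number of shared chromosomes).
    """
    a = pd.Series(per_chrom_abs_mfe, dtype=float)
    b = pd.Series(table, dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("missegregation probabilities must lie in [0, 1]")
    shared = a.index.intersection(b.index)
    dropped = set(a.index).symmetric_difference(b.index)
    if dropped:
        log.info("correlate_missegregation: dropped unmatched chromosomes %s",
                 sorted(dropped))
    if len(shared) < 3:
        raise UndefinedCorrelationError("fewer than 3 shared chromosomes")
    return pearson(a[shared].to_numpy(), b[shared].to_numpy()), len(shared)


def length_sensitivity(profiles: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Region ranking by mean MFE per window length; flags rank changes.

    Input maps window length -> profile.  The report has one row per
    length with the region order (most negative mean MFE first) and a
    boolean ``ordering_preserved`` against the first length.
    """
    if len(profiles) < 2:
        raise ValueError("need profiles at >= 2 window lengths")
    region_sets = [frozenset(p.region_label.unique()) for p in profiles.values()]
    if len(set(region_sets)) != 1:
        raise ValueError("profiles cover different region sets")
    rows = []
    reference: tuple[str, ...] | None = None
    for L in sorted(profiles):
        means = profiles[L].groupby("region_label").mfe.mean().sort_values()
        order = tuple(means.index)
        if reference is None:
            reference = order
        rows.append({
            "window_length": L,
            "region_order": " < ".join(order),
            "mean_mfe": dict(means),
            "ordering_preserved": order == reference,
        })
    return pd.DataFrame(rows)
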