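"""Moderated differential-expression calls per comparison.

Each of the four contrasts is fitted independently as a one-sample
linear model over its orientation-corrected replicate log2 ratios.
Per-transcript residual variances are shrunk toward a prior fitted
across all transcripts by moment-matching a scaled-F distribution
(empirical Bayes); the resulting moderated t-statistic gains the prior
degrees of freedom.  Transcripts are called regulated when the BH
adjusted p-value is below 0.05 *and* the mean log2 ratio exceeds 2 in
magnitude, and the regulated set is the union over the four contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, fit_scaled_f_prior, squeeze_variances
from .synthetic import COMPARISONS

logger = logging.getLogger(__name__)

_LARGE_DF = 1e6  # stands in for infinite prior degrees of freedom


@dataclass
class ExperimentDesign:
    """Four pairwise contrasts, each with >= 2 dye-swap replicates.

    ``orientations[comparison]`` lists one sign per replicate: +1 when
    channel 1 carried the numerator condition, -1 for the swapped dye
    orientation.
    """

    comparisons: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(COMPARISONS)
    )
    orientations: dict[str, list[int]] = field(
        default_factory=lambda: {c: [1, -1] for c in COMPARISONS}
    )

    def validate(self) -> None:
        if len(self.comparisons) != 4:
            raise ValueError("design must contain exactly 4 comparisons")
        for comp in self.comparisons:
            orient = self.orientations.get(comp, [])
            if len(orient) < 2:
                raise ValueError(f"comparison {comp!r} needs >= 2 replicates")
            if any(o not in (1, -1) for o in orient):
                raise ValueError(f"orientations for {comp!r} must be +1/-1")


def orientation_correct(ratios: pd.Series, orientation: int) -> pd.Series:
    """Flip the ratio sign of a dye-swapped hybridisation."""
    if orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1")
    return ratios * orientation


def moderated_one_sample(values: pd.DataFrame) -> pd.DataFrame:
    """Moderated one-sample t-tests, one row per transcript.

    ``values`` is a transcripts x replicates matrix of orientation-
    corrected log2 ratios (NaN for missing).  Transcripts observed in
    fewer than two replicates are excluded with a warning.  Returns a
    DataFrame with ``mean_log2, s2, df, s2_post, moderated_t, df_total,
    p, d0, s0_sq``.
    """
    x = values.to_numpy(dtype=float)
    n = np.sum(np.isfinite(x), axis=1)
    keep = n >= 2
    if (~keep).any():
        logger.warning(
            "%d transcripts present in <2 replicates excluded", int((~keep).sum())
        )
    x, n = x[keep], n[keep]
    idx = values.index[keep]
    mean = np.nanmean(x, axis=1)
    s2 = np.nanvar(x, axis=1, ddof=1)
    df = n - 1.0
    try:
        d0, s0_sq = fit_scaled_f_prior(s2, df)
    except ValueError:
        # degenerate: nearly all variances zero (noise-free limit)
        d0, s0_sq = np.inf, float(np.nanmean(s2))
    s2_post = squeeze_variances(s2, df, d0, s0_sq)
    se = np.sqrt(s2_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0),
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    df_total = df + (d0 if np.isfinite(d0) else _LARGE_DF)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "mean_log2": mean,
            "s2": s2,
            "df": df,
            "s2_post": s2_post,
            "moderated_t": t,
            "df_total": df_total,
            "p": p,
            "d0": d0,
            "s0_sq": s0_sq,
        },
        index=idx,
    )


def fit_moderated(
    replicate_ratios: dict[tuple[str, int], pd.DataFrame],
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Fit all four contrasts and BH-adjust within each.

    ``replicate_ratios`` maps ``(comparison_id, replicate)`` to a table
    with ``transcript_id`` and ``log2_ratio`` columns (raw channel-1 /
    channel-2 ratios; dye orientation is corrected here using the
    design).  Returns a long DataFrame with one row per transcript per
    comparison: ``transcript_id, comparison_id, mean_log2, moderated_t,
    p, p_adj, regulated`` (the ``regulated`` flag applies the joint
    p_adj < 0.05 and |mean_log2| > 2 criterion).
    """
    design = design or ExperimentDesign()
    design.validate()
    frames = []
    for comp in design.comparisons:
        cols = {}
        for rep_idx, orientation in enumerate(design.orientations[comp], start=1):
            key = (comp, rep_idx)
            if key not in replicate_ratios:
                raise ValueError(f"missing replicate table for {key}")
            tab = replicate_ratios[key].set_index("transcript_id")["log2_ratio"]
            cols[rep_idx] = orientation_correct(tab, orientation)
        mat = pd.DataFrame(cols)
        res = moderated_one_sample(mat)
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        res["comparison_id"] = comp
        res["regulated"] = (res["p_adj"] < 0.05) & (res["mean_log2"].abs() > 2.0)
        frames.append(res.reset_index(names="transcript_id"))
    return pd.concat(frames, ignore_index=True)


def select_regulated(
    results: pd.DataFrame,
    p_threshold: float = 0.05,
    log2_threshold: float = 2.0,
    exclude=(),
) -> tuple[list[str], pd.DataFrame]:
    """Union of regulated transcripts and their 4-contrast profile matrix.

    A transcript is selected when in at least one comparison its BH
    adjusted p-value is below ``p_threshold`` and its mean log2 ratio
    exceeds ``log2_threshold`` in magnitude.  ``exclude`` removes genes
    from the output (the regulator's own transcript is the motivating
    case).  The profile matrix holds ``mean_log2`` per comparison; genes
    lacking a finite value in any comparison are dropped with a warning.
    """
    hit = (results["p_adj"] < p_threshold) & (
        results["mean_log2"].abs() > log2_threshold
    )
    selected = set(results.loc[hit, "transcript_id"]) - set(exclude)
    profiles = results.pivot(
        index="transcript_id", columns="comparison_id", values="mean_log2"
    )
    profiles = profiles.reindex(sorted(selected))
    incomplete = profiles.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "%d regulated genes lack a ratio in some comparison; dropped",
            int(incomplete.sum()),
        )
        profiles = profiles.loc[~incomplete]
    profiles.columns.name = None
    profiles.index.name = "gene_id"
    return sorted(profiles.index), profiles
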