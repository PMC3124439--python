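"""Two-colour array pretreatment.

One hybridisation's GPR-like result table is reduced to per-transcript
log2 ratios in four steps:

1. a background threshold is computed from the "not found" features
   (mean + 2 sample standard deviations of their pooled channel means);
2. flagged and saturating spots are discarded;
3. the log-ratio ``M = log2(ch1/ch2)`` is normalised against the mean
   log-intensity ``A`` by a global intensity-dependent loess fit, with
   no background subtraction anywhere;
4. normalised ratios are averaged over each transcript's "detectable"
   probes lying in the coding sequence on the matching strand, and
   transcripts with fewer than two such probes are discarded.

A probe is "detectable" when its raw mean intensities are above the
background threshold: by default both channels must exceed it (a ratio
needs signal in both), with an "either"-channel variant selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import FLAG_NOT_FOUND, FLAG_OK

logger = logging.getLogger(__name__)


class NoNotFoundFeaturesError(ValueError):
    """No 'not found' features: the background threshold is undefined."""


@dataclass
class PreprocessConfig:
    saturation_ceiling: float = 65535.0  # 16-bit scanner ceiling
    lowess_frac: float = 0.3
    lowess_iterations: int = 3
    detectability: str = "both"  # or "either"
    min_spots_for_lowess: int = 10
    min_detectable_probes: int = 2

    def validate(self) -> None:
        if self.detectability not in ("both", "either"):
            raise ValueError("detectability must be 'both' or 'either'")
        if not 0 < self.lowess_frac <= 1:
            raise ValueError("lowess_frac must lie in (0, 1]")


def compute_background_threshold(not_found_intensities) -> float:
    """Mean + 2 sample standard deviations of the not-found intensities.

    A single value has SD 0 by convention; an empty list raises
    :class:`NoNotFoundFeaturesError`.
    """
    x = np.asarray(list(not_found_intensities), dtype=float)
    if x.size == 0:
        raise NoNotFoundFeaturesError(
            "no 'not found' features on this array; background threshold undefined"
        )
    sd = 0.0 if x.size == 1 else float(x.std(ddof=1))
    return float(x.mean() + 2.0 * sd)


def saturated_mask(table: pd.DataFrame, ceiling: float) -> pd.Series:
    return (table["F635_mean"] >= ceiling) | (table["F532_mean"] >= ceiling)


def normalize_global(
    ch1,
    ch2,
    frac: float = 0.3,
    iterations: int = 3,
    min_spots: int = 10,
) -> np.ndarray:
    """Loess-normalised log2 ratios.

    Fits an intensity-dependent trend of ``M = log2(ch1/ch2)`` on
    ``A = 0.5*log2(ch1*ch2)`` by locally weighted regression (tricube
    weights, robustness iterations) over all retained spots and returns
    ``M`` minus the fitted trend.  No background subtraction is applied.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.size < min_spots:
        raise ValueError(
            f"only {ch1.size} spots retained; need >= {min_spots} for the loess fit"
        )
    if np.any(ch1 <= 0) or np.any(ch2 <= 0):
        raise ValueError("intensities must be positive for log-ratio normalisation")
    m = np.log2(ch1 / ch2)
    a = 0.5 * np.log2(ch1 * ch2)
    fitted = sm.nonparametric.lowess(
        m, a, frac=frac, it=iterations, return_sorted=False
    )
    return m - fitted


def preprocess_hybridization(
    table: pd.DataFrame,
    probe_map: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Full pretreatment of one hybridisation result table.

    Returns a DataFrame ``transcript_id, log2_ratio, n_probes`` holding
    the mean normalised log2 ratio over each transcript's qualifying
    probes (detectable, in-coding, matching strand); transcripts with
    fewer than two qualifying probes are absent.
    """
    config = config or PreprocessConfig()
    config.validate()
    required = {"probe_id", "F635_mean", "F532_mean", "flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"result table missing columns: {sorted(missing)}")

    nf = table["flag"] == FLAG_NOT_FOUND
    pooled = np.concatenate(
        [table.loc[nf, "F635_mean"].to_numpy(), table.loc[nf, "F532_mean"].to_numpy()]
    )
    threshold = compute_background_threshold(pooled)

    sat = saturated_mask(table, config.saturation_ceiling)
    retained = table.loc[(table["flag"] == FLAG_OK) & ~sat].copy()
    retained["norm_m"] = normalize_global(
        retained["F635_mean"],
        retained["F532_mean"],
        frac=config.lowess_frac,
        iterations=config.lowess_iterations,
        min_spots=config.min_spots_for_lowess,
    )
    if config.detectability == "both":
        detectable = (retained["F635_mean"] > threshold) & (retained["F532_mean"] > threshold)
    else:
        detectable = (retained["F635_mean"] > threshold) | (retained["F532_mean"] > threshold)
    retained = retained.loc[detectable]
    return aggregate_transcripts(retained, probe_map, config)


def aggregate_transcripts(
    detectable_probes: pd.DataFrame,
    probe_map: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Average normalised ratios over each transcript's qualifying probes.

    ``detectable_probes`` must carry ``probe_id`` and ``norm_m`` for the
    probes that passed flag, saturation and detectability filters.
    Probes mapping to no transcript or lying outside the coding sequence
    (or on the non-matching strand) never contribute; unknown probes are
    warned about and ignored.
    """
    config = config or PreprocessConfig()
    pm = probe_map.set_index("probe_id")
    detectable_probes = detectable_probes.drop(
        columns=[c for c in ("transcript_id", "in_coding_on_matching_strand")
                 if c in detectable_probes.columns]
    )
    unknown = ~detectable_probes["probe_id"].isin(pm.index)
    if unknown.any():
        logger.warning(
            "%d probes reference no known transcript; ignored", int(unknown.sum())
        )
    merged = detectable_probes.loc[~unknown].join(
        pm[["transcript_id", "in_coding_on_matching_strand"]], on="probe_id"
    )
    merged = merged.loc[
        merged["in_coding_on_matching_strand"].astype(bool)
        & merged["transcript_id"].notna()
    ]
    grouped = merged.groupby("transcript_id")["norm_m"].agg(["mean", "size"])
    grouped = grouped.loc[grouped["size"] >= config.min_detectable_probes]
    out = grouped.reset_index().rename(
        columns={"mean": "log2_ratio", "size": "n_probes"}
    )
    return out.sort_values("transcript_id", ignore_index=True)
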