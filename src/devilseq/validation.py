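"""Amplicon-sequencing validation of predicted SNVs.

Deep amplicon data (~10^4-10^5x) lets a predicted variant allele be tested
against the platform's sequencing-error background. At each locus the two
bases that are neither the reference nor the predicted alternative measure
pure background error; their allele fractions, pooled across loci, are fitted
with a gamma distribution. A predicted alternative allele is called
validated when its VAF exceeds the fitted distribution's 95% cumulative-
probability point (configurable quantile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BackgroundModel",
    "background_vafs",
    "fit_background_model",
    "validate_alleles",
]


@dataclass
class BackgroundModel:
    """Gamma model of background (error) allele fractions."""

    shape: float
    scale: float
    n_obs: int
    method: str = "mle"          # "mle", "moments", or "degenerate"
    fallback_threshold: float | None = None

    def quantile(self, q: float) -> float:
        if self.method == "degenerate":
            return self.fallback_threshold if q < 1 else np.inf
        if q >= 1:
            return np.inf  # gamma support is unbounded above
        return float(stats.gamma.ppf(q, a=self.shape, scale=self.scale))


def background_vafs(loci: pd.DataFrame) -> np.ndarray:
    """Pool the two non-ref, non-alt base fractions from every locus.

    ``loci`` needs columns ``ref``, ``alt``, ``depth`` and ``count_A`` ..
    ``count_T`` (layout of
    :func:`devilseq.simulate.simulate_amplicon_experiment`).
    """
    if (loci["depth"] <= 0).any():
        raise ValueError("locus with zero depth")
    out = []
    for _, row in loci.iterrows():
        bg = [b for b in "ACGT" if b not in (row["ref"], row["alt"])]
        out.extend(row[f"count_{b}"] / row["depth"] for b in bg)
    return np.asarray(out, dtype=float)


def fit_background_model(loci: pd.DataFrame, min_obs: int = 10) -> BackgroundModel:
    """Maximum-likelihood gamma fit to the pooled background VAFs.

    Zero fractions (no error read seen) are replaced by the half-read
    pseudo-fraction 1/(2 x depth) so the MLE on the positive support stays
    finite. If the observations are (numerically) constant the fit is
    degenerate and the constant becomes a fallback threshold. Falls back to
    method-of-moments if the MLE fails.
    """
    vafs = background_vafs(loci)
    if len(vafs) < min_obs:
        raise ValueError(f"need >= {min_obs} background observations")
    if np.all(vafs == 0):
        raise ValueError("all background VAFs are zero; no error process to model")
    depths = np.repeat(loci["depth"].to_numpy(dtype=float), 2)
    vafs = np.where(vafs > 0, vafs, 1.0 / (2.0 * depths))
    if np.ptp(vafs) < 1e-12:
        return BackgroundModel(np.nan, np.nan, len(vafs), "degenerate",
                               fallback_threshold=float(vafs[0]))
    try:
        shape, _, scale = stats.gamma.fit(vafs, floc=0)
        method = "mle"
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise ValueError
    except Exception:
        mean, var = vafs.mean(), vafs.var(ddof=1)
        shape, scale, method = mean**2 / var, var / mean, "moments"
    return BackgroundModel(float(shape), float(scale), len(vafs), method)


def validate_alleles(loci: pd.DataFrame, model: BackgroundModel,
                     q: float = 0.95) -> pd.DataFrame:
    """Call each predicted alternative allele validated or not.

    Validated iff the alt VAF strictly exceeds the background model's
    ``q``-quantile. Returns a per-locus frame (locus, alt VAF, threshold,
    validated) with the summary counts in ``result.attrs``.
    """
    if (loci["depth"] <= 0).any():
        raise ValueError("locus with zero depth")
    threshold = model.quantile(q)
    alt_vaf = np.array([row[f"count_{row['alt']}"] / row["depth"]
                        for _, row in loci.iterrows()])
    out = pd.DataFrame({
        "locus": loci["locus"].to_numpy() if "locus" in loci.columns else loci.index,
        "alt_vaf": alt_vaf,
        "threshold": threshold,
        "validated": alt_vaf > threshold,
    })
    out.attrs["n_validated"] = int(out["validated"].sum())
    out.attrs["n_tested"] = len(out)
    return out
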