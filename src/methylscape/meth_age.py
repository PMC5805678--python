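"""Methylation-age prediction with a pluggable linear clock.

Clock coefficients are never bundled; any clock in the TSV format of
:mod:`methylscape.io` can be supplied.  The age transform is the standard
piecewise log-linear form with a configurable adult-age pivot:

    forward(a) = log(a + 1) - log(adult + 1)      for a <= adult
                 (a - adult) / (adult + 1)        otherwise

which is continuous and strictly increasing, with an exact inverse.
Gap sign convention: gap = predicted - chronological, so a negative gap
means a younger-looking methylome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BetaMatrix, ClockModel, SampleSheet

LOW_CONFIDENCE_MISSING_FRACTION = 0.20


def age_transform(age, adult_age: float = 20.0):
    """Piecewise log-linear transform of age in years."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValueError("age must be > -1 years")
    if adult_age <= 0:
        raise ValueError("adult_age must be positive")
    out = np.where(
        age <= adult_age,
        np.log(age + 1.0) - np.log(adult_age + 1.0),
        (age - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def age_transform_inverse(score, adult_age: float = 20.0):
    """Exact inverse of :func:`age_transform`."""
    if adult_age <= 0:
        raise ValueError("adult_age must be positive")
    score = np.asarray(score, dtype=float)
    out = np.where(
        score <= 0,
        (adult_age + 1.0) * np.exp(score) - 1.0,
        (adult_age + 1.0) * score + adult_age,
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class AgePrediction:
    table: pd.DataFrame  # index sample_id; predicted_age, missing_fraction, low_confidence
    missing_probes: list[str] = field(default_factory=list)

    @property
    def predicted(self) -> pd.Series:
        return self.table["predicted_age"]


def predict_age(beta: BetaMatrix, clock: ClockModel) -> AgePrediction:
    """Apply a linear clock to each sample.

    Clock probes absent from the matrix contribute nothing and are reported;
    per-sample missing values among present clock probes are imputed with the
    probe's cross-sample mean.  Samples missing more than 20% of the clock
    probes (absent or NA) are flagged low-confidence.  Zero resolvable clock
    probes is an error.
    """
    present = clock.probe_ids.intersection(beta.probe_ids)
    if len(present) == 0:
        raise ValueError("no clock probes present in the beta matrix")
    missing_probes = clock.probe_ids.difference(beta.probe_ids).tolist()
    sub = beta.df.loc[present]
    na = sub.isna()
    filled = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    w = clock.weights.loc[present]
    score = clock.intercept + filled.mul(w, axis=0).sum(axis=0, skipna=False)
    n_clock = len(clock.probe_ids)
    missing_per_sample = (len(missing_probes) + na.sum(axis=0)) / n_clock
    table = pd.DataFrame(
        {
            "predicted_age": age_transform_inverse(score.to_numpy(), clock.adult_age),
            "missing_fraction": missing_per_sample,
            "low_confidence": missing_per_sample > LOW_CONFIDENCE_MISSING_FRACTION,
        },
        index=beta.sample_ids,
    )
    return AgePrediction(table=table, missing_probes=missing_probes)


@dataclass
class AgeGapResult:
    per_sample: pd.DataFrame  # predicted_age, chronological_age, gap
    per_group: pd.Series  # group -> mean gap
    n_missing_age: int = 0


def age_gap(predicted, samplesheet: SampleSheet) -> AgeGapResult:
    """Per-sample and per-group gap between predicted and chronological age.

    Samples without a chronological age are excluded from group means and
    counted in the report.
    """
    if isinstance(predicted, AgePrediction):
        predicted = predicted.predicted
    common = predicted.index.intersection(samplesheet.sample_ids)
    chron = samplesheet.df.loc[common, "chronological_age"]
    table = pd.DataFrame(
        {
            "predicted_age": predicted.loc[common],
            "chronological_age": chron,
            "group": samplesheet.df.loc[common, "group"],
        }
    )
    table["gap"] = table["predicted_age"] - table["chronological_age"]
    has_age = table["chronological_age"].notna()
    per_group = table[has_age].groupby("group")["gap"].mean()
    per_group.name = "mean_gap"
    return AgeGapResult(
        per_sample=table,
        per_group=per_group,
        n_missing_age=int((~has_age).sum()),
    )
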