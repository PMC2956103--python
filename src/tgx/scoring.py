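"""Gene set-level expression scoring: TGP1 scores and quality-weighted D-scores.

Both scores summarize per-probe log2 expression changes (treated minus
control group means) over a biomarker gene set:

* TGP1 score = direction x magnitude, where direction = (n_up - n_down)/n
  and magnitude = mean |e_i|.  It is positive for uniform up-regulation,
  negative for uniform down-regulation and approaches zero when the probes
  disagree in direction.
* D-score = C * mean(w_i * e_i), where w_i in [0, 1] is a per-probe data
  quality weight derived from microarray detection calls (Present = 1,
  Marginal = 0.5, Absent = 0) and C is a scale constant (default 10, so a
  uniform 2-fold change at full quality scores 20).  Low-quality probes are
  discounted rather than allowed to corrupt the score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DesignTable, ExpressionBundle, GeneSetCollection, ScoreTable

log = logging.getLogger(__name__)

#: Detection-call quality weights (Affymetrix P/M/A convention).
CALL_WEIGHTS = {"P": 1.0, "M": 0.5, "A": 0.0}

#: Default D-score scale constant: a uniform 1-log2-unit change at full
#: quality scores 10; the radar-chart reference circle sits at 20.
DEFAULT_SCALE = 10.0


@dataclass
class GeneChangeTable:
    """Per-probe signed effects and quality weights for one condition."""

    condition_id: str
    effects: pd.Series   # e_i = mean treated log2 - mean control log2
    weights: pd.Series   # w_i in [0, 1]

    def __post_init__(self) -> None:
        if not self.effects.index.equals(self.weights.index):
            raise ValidationError("effects and weights must share a probe index")
        if not np.isfinite(self.effects.to_numpy()).all():
            raise ValidationError("non-finite effect in gene-change table")
        w = self.weights.to_numpy()
        if ((w < 0) | (w > 1)).any() or not np.isfinite(w).all():
            raise ValidationError("quality weights must lie in [0, 1]")


def compute_changes(bundle: ExpressionBundle, design: DesignTable,
                    condition_id: str) -> GeneChangeTable:
    """Per-probe effect and quality weight for one condition.

    Effect = mean treated log2 minus mean control log2.  Weight = mean call
    weight over *all* samples of the condition (controls included): a probe
    must be reliably detected throughout the comparison to count fully.
    """
    treated = design.samples(condition_id, "treated")
    control = design.samples(condition_id, "control")
    all_samples = control + treated
    missing = [s for s in all_samples if s not in bundle.values.columns]
    if missing:
        raise ValidationError(
            f"condition {condition_id!r}: sample(s) missing from expression data: {missing}"
        )
    vals = bundle.values[all_samples]
    if not np.isfinite(vals.to_numpy()).all():
        bad = vals.index[(~np.isfinite(vals.to_numpy())).any(axis=1)][0]
        raise ValidationError(
            f"condition {condition_id!r}: non-finite value for probe {bad!r}"
        )
    effects = bundle.values[treated].mean(axis=1) - bundle.values[control].mean(axis=1)
    weight_codes = bundle.calls[all_samples].apply(
        lambda col: col.map(CALL_WEIGHTS), axis=0
    )
    weights = weight_codes.mean(axis=1)
    return GeneChangeTable(condition_id=condition_id,
                           effects=effects.astype(float),
                           weights=weights.astype(float))


def _retained_effects(changes: GeneChangeTable, probes: list[str],
                      min_abs_effect: float = 0.0) -> pd.Index:
    """Probes from the set usable for scoring; warns on drops, errors if none."""
    if not probes:
        raise ValidationError("gene set is empty")
    present = [p for p in dict.fromkeys(probes) if p in changes.effects.index]
    n_missing = len(dict.fromkeys(probes)) - len(present)
    if n_missing:
        log.warning("condition %s: %d set member(s) absent from the array, dropped",
                    changes.condition_id, n_missing)
    if not present:
        raise ValidationError(
            f"condition {changes.condition_id!r}: no gene-set member is present on the array"
        )
    idx = pd.Index(present)
    if min_abs_effect > 0:
        idx = idx[changes.effects.loc[idx].abs().to_numpy() >= min_abs_effect]
    return idx


def tgp1_score(changes: GeneChangeTable, probes: list[str],
               min_abs_effect: float = 0.0) -> float:
    """Direction x magnitude score over the retained set members.

    Ties (e_i = 0) count in n but in neither direction tally, pulling the
    direction index toward zero.  Returns 0.0 if an optional minimum-effect
    filter removes every probe.
    """
    idx = _retained_effects(changes, probes, min_abs_effect)
    if len(idx) == 0:
        return 0.0
    e = changes.effects.loc[idx].to_numpy()
    n = e.size
    direction = (np.count_nonzero(e > 0) - np.count_nonzero(e < 0)) / n
    magnitude = np.abs(e).mean()
    return float(direction * magnitude)


def d_score(changes: GeneChangeTable, probes: list[str],
            scale: float = DEFAULT_SCALE, min_abs_effect: float = 0.0) -> float:
    """Quality-weighted mean change times the scale constant.

    All-Absent probes (w = 0) contribute nothing to the numerator; they still
    count in the 1/n normalization, so padding a set with undetected probes
    dilutes — never inflates — the score.
    """
    idx = _retained_effects(changes, probes, min_abs_effect)
    if len(idx) == 0:
        return 0.0
    e = changes.effects.loc[idx].to_numpy()
    w = changes.weights.loc[idx].to_numpy()
    # fsum: correctly rounded, so exactly matched +d/-d pairs cancel to 0.0
    return float(scale * math.fsum(w * e) / e.size)


def score_all(bundle: ExpressionBundle, design: DesignTable,
              sets: GeneSetCollection, method: str = "dscore",
              scale: float = DEFAULT_SCALE,
              min_abs_effect: float = 0.0) -> ScoreTable:
    """Dense gene set x condition score matrix (deterministic given inputs)."""
    if method not in ("dscore", "tgp1"):
        raise ValidationError(f"unknown scoring method {method!r}")
    design.check_against(bundle)
    conditions = design.conditions()
    out = pd.DataFrame(index=pd.Index(sets.names(), name="gene_set"),
                       columns=pd.Index(conditions, name="condition_id"),
                       dtype=float)
    for cond in conditions:
        try:
            changes = compute_changes(bundle, design, cond)
            for name, probes in sets.sets.items():
                if method == "dscore":
                    out.loc[name, cond] = d_score(changes, probes, scale, min_abs_effect)
                else:
                    out.loc[name, cond] = tgp1_score(changes, probes, min_abs_effect)
        except ValidationError as exc:
            raise ValidationError(f"condition {cond!r}: {exc}") from exc
    return ScoreTable(scores=out, method=method, scale=scale)
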