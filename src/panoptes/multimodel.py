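"""Indirect POLE classification from the other molecular-subtype models.

The POLE ultramutated subtype lacks a direct single-model classifier strong
enough for clinical use; instead, the negative prediction scores of the
CNV-H, CNV-L and MSI-high models are aggregated: a patient that none of the
other three subtype models claims is likely POLE.  The composed score is
``agg_m (1 - s_m)`` over member models m, with arithmetic mean as the
default aggregation (product offered as an option); it is monotone
decreasing in every member score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import pandas as pd

DEFAULT_MEMBERS = ("CNV-H", "CNV-L", "MSI-high")


@dataclass(frozen=True)
class MultiModelConfig:
    members: tuple[str, ...] = DEFAULT_MEMBERS
    aggregation: str = "mean"

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("need at least 2 member models")
        if self.aggregation not in ("mean", "product"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def pole_score(
    member_scores: pd.DataFrame, cfg: MultiModelConfig | None = None
) -> pd.Series:
    """Compose per-patient (or per-tile) POLE scores.

    ``member_scores`` is a wide table indexed by patient (or tile-set) id
    with one column per member task holding positive-class probabilities.
    Rows with any missing member score are dropped with a warning.
    """
    cfg = cfg or MultiModelConfig()
    missing_cols = [m for m in cfg.members if m not in member_scores.columns]
    if missing_cols:
        raise ValueError(f"missing member columns {missing_cols}")
    sub = member_scores[list(cfg.members)]
    if ((sub < 0) | (sub > 1)).any().any():
        raise ValueError("member scores must lie in [0, 1]")
    complete = sub.dropna()
    if len(complete) < len(sub):
        dropped = sorted(set(sub.index) - set(complete.index))
        warnings.warn(
            f"dropping {len(dropped)} rows with missing member scores: {dropped[:5]}..."
        )
    comp = 1.0 - complete
    if cfg.aggregation == "mean":
        return comp.mean(axis=1).rename("pole_score")
    return comp.prod(axis=1).rename("pole_score")


def compose_pole_table(
    member_preds: dict[str, pd.DataFrame],
    level: str = "per_patient",
    cfg: MultiModelConfig | None = None,
) -> pd.DataFrame:
    """Build a POLE prediction table from member prediction tables.

    ``member_preds`` maps member task name -> a prediction table carrying
    true POLE labels in ``true_label``.  At per-tile level, members are
    paired by ``tile_set_id`` (requires a shared tiling); at per-patient
    level, member scores are first averaged per patient.
    Returns a table in the evaluation module's schema, scoreable unchanged.
    """
    from .evaluation import patient_scores

    cfg = cfg or MultiModelConfig(members=tuple(member_preds.keys()))
    key = "patient_id" if level == "per_patient" else "tile_set_id"
    frames = {}
    labels = None
    for name, preds in member_preds.items():
        t = patient_scores(preds) if level == "per_patient" else preds
        t = t.set_index(key if level == "per_patient" else "tile_set_id")
        frames[name] = t["score"]
        lab = t["true_label"]
        labels = lab if labels is None else labels.combine_first(lab)
    wide = pd.DataFrame(frames)
    score = pole_score(wide, cfg)
    out = pd.DataFrame({"score": score, "true_label": labels.loc[score.index]})
    out.index.name = key
    out = out.reset_index()
    if level == "per_patient":
        out["patient_id"] = out[key]
        out["slide_id"] = out[key]
        out["tile_set_id"] = out[key]
    else:
        first = next(iter(member_preds.values()))
        meta = first.set_index("tile_set_id")[["patient_id", "slide_id"]]
        out = out.join(meta, on="tile_set_id")
    return out[["patient_id", "slide_id", "tile_set_id", "score", "true_label"]]
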