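"""Indicator ("designer") panels: transcripts whose z-scores separate the
diapause (field) from the reproductive (culture) program with no overlap.

A transcript passes the field_up filter when its smallest z-score among
field samples is strictly greater than its largest z-score among culture
samples (and symmetrically for culture_up).  Candidates are drawn from
DEGs annotated to the configured GO terms; panels record per-term
provenance for the Fig.-9-style multi-term filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class IndicatorPanel:
    direction: str  # field_up | culture_up
    per_term: dict[str, frozenset]
    transcripts: frozenset
    z_summary: pd.DataFrame  # per transcript: min/max z per program

    def __len__(self) -> int:
        return len(self.transcripts)


def nonoverlap_filter(
    z: ExpressionMatrix,
    candidates: Iterable[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> frozenset:
    """Transcripts with min z over group_a strictly above max z over group_b.

    Strict inequality: a tie counts as overlap and excludes the transcript.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    ids = [t for t in candidates if t in z.values.index]
    if not ids:
        return frozenset()
    sub = z.values.loc[ids]
    min_a = sub[group_a].min(axis=1)
    max_b = sub[group_b].max(axis=1)
    return frozenset(sub.index[min_a > max_b])


def build_panel(
    z: ExpressionMatrix,
    deg_sets: Mapping[str, Iterable[str]],
    samples: pd.DataFrame,
    direction: str,
) -> IndicatorPanel:
    """Union of per-term non-overlap filters, field vs culture pooled over
    timepoints.  direction 'field_up' keeps transcripts strictly higher in
    every field sample; 'culture_up' the reverse."""
    if direction not in ("field_up", "culture_up"):
        raise ValueError(f"unknown direction: {direction!r}")
    field = [s for s in z.values.columns if samples.loc[s, "source"] == "field"]
    culture = [s for s in z.values.columns if samples.loc[s, "source"] == "culture"]
    up, down = (field, culture) if direction == "field_up" else (culture, field)

    per_term = {
        term: nonoverlap_filter(z, ids, up, down) for term, ids in deg_sets.items()
    }
    transcripts = frozenset().union(*per_term.values()) if per_term else frozenset()
    ids = sorted(transcripts)
    summary = pd.DataFrame(
        {
            "min_field_z": z.values.loc[ids, field].min(axis=1),
            "max_field_z": z.values.loc[ids, field].max(axis=1),
            "min_culture_z": z.values.loc[ids, culture].min(axis=1),
            "max_culture_z": z.values.loc[ids, culture].max(axis=1),
        }
    )
    return IndicatorPanel(direction, per_term, transcripts, summary)


def write_panel(panel: IndicatorPanel, path: str | Path) -> None:
    rows = []
    for t in sorted(panel.transcripts):
        terms = sorted(term for term, ids in panel.per_term.items() if t in ids)
        row = {"transcript_id": t, "direction": panel.direction,
               "source_terms": ";".join(terms)}
        row.update(panel.z_summary.loc[t].to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
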