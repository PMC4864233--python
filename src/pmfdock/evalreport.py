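"""Enrichment, recall/precision and difficulty analyses over rankings.

These are set-level summaries of how well an energy-based ranking pulls
near-native decoys to the top: per-category composition of the top-k
selections, mean Recall (fnat) and Precision (1 - fnonnat) per selection,
and the target difficulty (fraction of acceptable-or-better decoys in the
whole set).  All numeric outputs are plain tables; the optional scatter
figure is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quality import QualityRecord, CATEGORIES

ACCEPTABLE_OR_BETTER = ("High", "Medium", "Acceptable")
DEFAULT_TOPK = (1, 5, 10, 20, 100)

__all__ = ["EnrichmentReport", "enrichment", "recall_precision",
           "scatter_table", "difficulty", "enrichment_report",
           "ACCEPTABLE_OR_BETTER", "DEFAULT_TOPK"]


def _check_records(selection, records):
    missing = [i for i in selection if i not in records]
    if missing:
        raise KeyError(f"no quality record for: {missing[:5]}")


def enrichment(selection: list, records: dict) -> dict:
    """Per-category fractions of a selection of decoy ids."""
    if not selection:
        raise ValueError("empty selection")
    _check_records(selection, records)
    n = len(selection)
    return {c: sum(records[i].category == c for i in selection) / n
            for c in CATEGORIES}


def recall_precision(selection: list, records: dict) -> tuple:
    """(mean fnat, mean 1 - fnonnat) over a selection."""
    if not selection:
        raise ValueError("empty selection")
    _check_records(selection, records)
    rec = float(np.mean([records[i].fnat for i in selection]))
    prec = float(np.mean([1.0 - records[i].fnonnat for i in selection]))
    return rec, prec


def difficulty(records: dict) -> float:
    """Fraction of acceptable-or-better decoys in the full set.

    Low values mean a hard target (few near-native decoys to find)."""
    if not records:
        raise ValueError("no records")
    return sum(r.category in ACCEPTABLE_OR_BETTER
               for r in records.values()) / len(records)


def scatter_table(records: dict, scores: dict) -> pd.DataFrame:
    """Plot-ready (decoy id, I-rms, dG_off) rows, key-sorted.

    Raises ``KeyError`` naming the first id present in one map but not the
    other."""
    only_r = sorted(set(records) - set(scores))
    only_s = sorted(set(scores) - set(records))
    if only_r or only_s:
        missing = (only_r or only_s)[0]
        raise KeyError(f"id {missing!r} lacks a "
                       f"{'score' if only_r else 'quality record'}")
    rows = [(i, records[i].i_rms, scores[i]) for i in sorted(records)]
    return pd.DataFrame(rows, columns=["decoy_id", "i_rms_A", "dg_off"])


@dataclass(frozen=True)
class EnrichmentReport:
    """All selection-level summaries for one ranking."""

    difficulty: float
    full_fractions: dict
    selections: dict = field(default_factory=dict)
    # selections: name -> {"fractions": {...}, "recall": x, "precision": y,
    #                      "n": k}

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def row(name, n, fr, rec, prec):
            r = {"selection": name, "n": n, **{c.lower(): fr[c]
                                               for c in CATEGORIES}}
            r["acceptable_or_better"] = sum(fr[c] for c in
                                            ACCEPTABLE_OR_BETTER)
            r["recall"], r["precision"] = rec, prec
            rows.append(r)

        for name, s in self.selections.items():
            row(name, s["n"], s["fractions"], s["recall"], s["precision"])
        return pd.DataFrame(rows)


def enrichment_report(ranking, records: dict,
                      topk=DEFAULT_TOPK) -> EnrichmentReport:
    """Build the full report for a ranking (top-k sets, top half, full set).

    ``ranking`` is a :class:`~pmfdock.protocol.Ranking`; every ranked id
    must have a quality record."""
    from .protocol import top_k, select_best_half

    ids = list(ranking.ids)
    _check_records(ids, records)
    selections = {}

    def add(name, sel):
        fr = enrichment(sel, records)
        rec, prec = recall_precision(sel, records)
        selections[name] = {"fractions": fr, "recall": rec,
                            "precision": prec, "n": len(sel)}

    add("full", ids)
    for k in topk:
        add(f"top{k}", top_k(ranking, k))
    half = [i for i in ids if i in select_best_half(ranking)]
    add("top_half", half)

    return EnrichmentReport(difficulty=difficulty(records),
                            full_fractions=enrichment(ids, records),
                            selections=selections)


def plot_scatter(table: pd.DataFrame, path) -> None:
    """dG_off vs I-rms scatter (cosmetic; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["i_rms_A"], table["dg_off"], s=12, alpha=0.7)
    ax.set_xlabel("I-rms (A)")
    ax.set_ylabel("dG_off (kJ/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
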