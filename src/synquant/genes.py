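"""Gene-program statistics: expression filtering, DEG calls, candidate
scoring, and gene-set overlap enrichment.

These are the downstream statistics applied to a differential-expression
table (gene id, fold change + direction, p-value, expression level):

* genes count as *expressed* when their RPKM exceeds the 99th percentile
  of an intergenic background distribution (a literal ``0.99 × value``
  reading of the same rule is available as an alternate mode);
* a *DEG* satisfies p ≤ 0.05 and fold change ≥ 1.5, both inclusive;
* candidate genes are ranked by the number of binary selection criteria
  they meet (0–4), after removing genes below an expression floor
  (FPKM < 5);
* overlap with a reference gene list (e.g. autism-associated genes) is
  summarized as fold enrichment over chance and a two-sided Fisher's
  exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneRecord:
    """One gene's differential-expression summary.

    ``fold_change`` is the positive ratio (≥ larger/smaller convention);
    ``direction`` is ``"up"`` or ``"down"`` in mutant vs control.
    """

    gene_id: str
    fold_change: float
    p_value: float
    direction: str = "up"
    rpkm: float = 0.0
    criteria: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"{self.gene_id}: p_value outside [0, 1]")
        if not (self.fold_change > 0):
            raise ValueError(f"{self.gene_id}: fold_change must be > 0")
        if self.direction not in ("up", "down"):
            raise ValueError(f"{self.gene_id}: direction must be 'up' or 'down'")


@dataclass
class EnrichmentResult:
    """Gene-set overlap enrichment."""

    overlap_count: int
    query_size: int
    reference_size: int
    universe_size: int
    fold_enrichment: float
    p_value: float


def filter_expressed(
    genes: list[GeneRecord],
    background_values: np.ndarray,
    mode: str = "percentile",
) -> tuple[list[GeneRecord], dict]:
    """Keep genes whose expression exceeds the intergenic background.

    ``mode="percentile"`` (default): RPKM must exceed the 99th percentile
    (linear interpolation) of the background distribution.
    ``mode="scalar"``: the literal reading — RPKM > 0.99 × a single
    background value (the background's mean is used when several values
    are supplied).

    Returns the kept genes and a metadata dict recording the mode and the
    effective cutoff.
    """
    bg = np.asarray(background_values, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background")
    if mode == "percentile":
        cutoff = float(np.percentile(bg, 99))
    elif mode == "scalar":
        cutoff = 0.99 * float(bg.mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = [g for g in genes if g.rpkm > cutoff]
    return kept, {"mode": mode, "cutoff": cutoff, "n_background": int(bg.size)}


def classify_deg(
    genes: list[GeneRecord], p_max: float = 0.05, fc_min: float = 1.5
) -> dict:
    """Split genes into up/down DEG lists at inclusive thresholds.

    A gene is differentially expressed iff ``p <= p_max`` and
    ``fold_change >= fc_min`` (both inclusive, so boundary genes count).
    Returns ``{"up": [...], "down": [...], "proportion_down": float}``;
    the proportion is NaN when there are no DEGs.
    """
    up = [g for g in genes if g.p_value <= p_max and g.fold_change >= fc_min and g.direction == "up"]
    down = [g for g in genes if g.p_value <= p_max and g.fold_change >= fc_min and g.direction == "down"]
    n = len(up) + len(down)
    return {
        "up": up,
        "down": down,
        "proportion_down": len(down) / n if n else float("nan"),
    }


def score_candidates(
    genes: list[GeneRecord],
    criteria_names: list[str],
    expression_floor: float = 5.0,
    min_score: int = 0,
) -> pd.DataFrame:
    """Rank candidate genes by the number of selection criteria they meet.

    Genes with expression below ``expression_floor`` (FPKM < floor) are
    removed before scoring.  Each criterion contributes 1 point when met;
    the table is sorted by score descending, ties alphabetical by gene id,
    and restricted to ``score >= min_score``.
    """
    rows = []
    for g in genes:
        missing = [c for c in criteria_names if c not in g.criteria]
        if missing:
            raise KeyError(f"{g.gene_id}: missing criteria {missing}")
        if g.rpkm < expression_floor:
            continue
        score = sum(int(bool(g.criteria[c])) for c in criteria_names)
        rows.append(
            {"gene_id": g.gene_id, "score": score}
            | {c: bool(g.criteria[c]) for c in criteria_names}
        )
    df = pd.DataFrame(rows, columns=["gene_id", "score", *criteria_names])
    df = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
    return df[df["score"] >= min_score].reset_index(drop=True)


def overlap_enrichment(
    query: set[str] | list[str],
    reference: set[str] | list[str],
    universe_size: int,
) -> EnrichmentResult:
    """Fold enrichment of a query gene list in a reference gene set.

    Fold enrichment compares the observed overlap proportion with the
    chance of drawing a reference gene from the universe:
    ``(k/|query|) / (|reference|/universe)``.  Significance is a two-sided
    Fisher's exact test on the 2×2 table
    ``[[k, |query|−k], [|reference|−k, U−|query|−|reference|+k]]``
    (two-sided rule: sum of hypergeometric probabilities ≤ the observed
    table's probability).
    """
    q = set(query)
    r = set(reference)
    if not q:
        raise ValueError("empty query list")
    if universe_size < len(q | r):
        raise ValueError("universe smaller than the union of the two lists")
    k = len(q & r)
    table = [
        [k, len(q) - k],
        [len(r) - k, universe_size - len(q) - len(r) + k],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    fold = (k / len(q)) / (len(r) / universe_size)
    return EnrichmentResult(
        overlap_count=k,
        query_size=len(q),
        reference_size=len(r),
        universe_size=universe_size,
        fold_enrichment=float(fold),
        p_value=float(p),
    )


def genes_from_table(df: pd.DataFrame, criteria_names: list[str] | None = None) -> list[GeneRecord]:
    """Build :class:`GeneRecord` objects from a tidy gene table.

    Expected columns: ``gene_id``, ``fold_change``, ``p_value``,
    ``direction``; optional ``rpkm`` and one boolean column per criterion.
    """
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                fold_change=float(d["fold_change"]),
                p_value=float(d["p_value"]),
                direction=str(d.get("direction", "up")),
                rpkm=float(d.get("rpkm", 0.0)),
                criteria={c: bool(d[c]) for c in (criteria_names or []) if c in d},
            )
        )
    return out
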