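"""Co-expression flags and generic term enrichment.

Expression profiles come as a gene x tissue matrix (arbitrary units,
>= 3 tissues for testable correlations).  Co-expression between two
co-localizing genes is declared from the Pearson correlation of their
tissue profiles; by default the flag is one-sided (positive correlation
only — co-regulation, not anti-regulation), with a two-sided option.

Term enrichment is a foreground-vs-background Fisher exact test per
term with Benjamini-Hochberg control, agnostic to where the annotation
(GO or otherwise) came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Expression levels for genes across tissues."""

    values: pd.DataFrame  # index: gene ids, columns: tissue labels

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need >= 2 tissues")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class PairFlag:
    gene_a: str
    gene_b: str
    r: float | None
    p: float | None
    coregulated: bool
    testable: bool = True


def coexpression_flag(
    group: list[str],
    expr: ExpressionMatrix,
    alpha: float = 0.01,
    two_sided: bool = False,
) -> tuple[list[PairFlag], bool]:
    """Flag co-regulated gene pairs within a co-localizing group.

    For every pair, the Pearson r of tissue profiles and its p-value;
    a pair is co-regulated when p < alpha (one-sided positive by
    default).  Returns the per-pair flags and a group verdict: True when
    every testable pair is co-regulated and at least one pair exists.

    A zero-variance profile has no defined correlation; such pairs are
    reported not testable and never co-regulated.
    """
    if alpha not in (0.01, 0.05):
        raise ValueError("alpha must be 0.01 or 0.05")
    missing = [g for g in group if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    if expr.values.shape[1] < 3:
        raise ValueError("need >= 3 tissues for correlation testing")
    flags = []
    for a, b in combinations(group, 2):
        xa, xb = expr.profile(a), expr.profile(b)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            flags.append(PairFlag(a, b, None, None, False, testable=False))
            continue
        r, p_two = stats.pearsonr(xa, xb)
        if two_sided:
            p = p_two
        else:
            p = p_two / 2 if r > 0 else 1 - p_two / 2
        flags.append(PairFlag(a, b, float(r), float(p), bool(p < alpha)))
    verdict = bool(flags) and all(f.coregulated for f in flags if f.testable) and any(
        f.testable for f in flags
    )
    return flags, verdict


# ---------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------

def load_terms(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV ``gene_id<TAB>term`` into a gene->terms dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term"]):
        out.setdefault(g, set()).add(t)
    return out


def term_enrichment(
    foreground: set[str] | list[str],
    background: set[str] | list[str],
    terms: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment of foreground vs background.

    The 2x2 table contrasts the foreground against the rest of the
    background (background must contain the foreground).  Terms absent
    from both sets are excluded.  Columns: term, fg_with, fg_without,
    bg_with, bg_without, odds_ratio, p, fdr, significant (BH FDR <=
    alpha).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    rest = bg - fg
    vocab = sorted({t for g in bg for t in terms.get(g, ())})
    rows = []
    for term in vocab:
        a = sum(1 for g in fg if term in terms.get(g, ()))
        b = len(fg) - a
        c = sum(1 for g in rest if term in terms.get(g, ()))
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows, columns=["term", "fg_with", "fg_without", "bg_with", "bg_without",
                       "odds_ratio", "p"]
    )
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["fdr"] <= alpha
    else:
        df["fdr"] = []
        df["significant"] = []
    return df.sort_values("p", kind="stable").reset_index(drop=True)
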