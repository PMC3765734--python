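"""Expression quantification and count-based differential expression.

Tag copy number is the abundance measure: a gene's count in a library is
the summed clean count of the tags unambiguously assigned to it.  Counts
are normalized to tags-per-million (TPM; 1e6 * count / library depth) and
optionally to RPKM (1e9 * count / (depth * transcript length)).  RPKM is
retained for fidelity to the profiling literature but, with a single tag
site per transcript, tag yield does not scale with transcript length, so
TPM is the default reported scale.

Differential expression between two libraries without replicates uses the
exact tag-count test of the Audic-Claverie tradition: under the null that a
gene is equally expressed in both libraries, its count in library B given
the pooled count n = x + y is Binomial(n, N2/(N1+N2)) where N1, N2 are the
library depths.  The two-sided p-value doubles the smaller exact tail
(capped at 1); this conditional form is exactly symmetric under swapping
the libraries.  Benjamini-Hochberg FDR is applied across genes observed in
the pair, and a gene is called up/down only when both FDR <= alpha and
|log2 fold change| >= lfc_min (fold change on TPM with pseudocount 1, so
unequal depths compare fairly).

Cross-species expression patterns: a gene whose between-species comparison
is significant in at least one developmental stage is classed "D"
(different); otherwise "S" (similar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .processing import STAGES


def normalize(
    counts: pd.DataFrame,
    library_depths: pd.Series | dict | None = None,
    transcript_lengths: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """TPM (and RPKM when lengths are given) from a gene x library count matrix.

    ``library_depths`` defaults to the matrix column sums; pass the
    library's clean-tag totals to normalize against all clean tags rather
    than only the mapped ones.
    """
    if library_depths is None:
        depths = counts.sum(axis=0).astype(float)
    else:
        depths = pd.Series(library_depths, dtype=float).reindex(counts.columns)
    if (depths <= 0).any() or depths.isna().any():
        bad = list(depths.index[(depths <= 0) | depths.isna()])
        raise ValueError(f"non-positive or missing depth for libraries: {bad}")
    tpm = counts.div(depths, axis=1) * 1e6
    rpkm = None
    if transcript_lengths is not None:
        lengths = pd.Series(transcript_lengths, dtype=float).reindex(counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            bad = list(lengths.index[lengths.isna() | (lengths <= 0)])
            raise ValueError(f"missing or non-positive transcript length for genes: {bad}")
        rpkm = counts.div(depths, axis=1).div(lengths, axis=0) * 1e9
    return tpm, rpkm


def ac_test(x, n1, y, n2):
    """Two-sided exact tag-count p-value comparing count x (depth n1) with y (depth n2).

    Conditional on the pooled count, y ~ Binomial(x + y, n2/(n1 + n2)) under
    equal expression; the p-value doubles the smaller exact tail, capped at
    1.  Accepts scalars or arrays (vectorized).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise ValueError("library depths must be positive")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be nonnegative")
    n = x + y
    q = n2 / (n1 + n2)
    lower = stats.binom.cdf(y, n, q)
    upper = stats.binom.sf(y - 1, n, q)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.where(n == 0, 1.0, p)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class DECall:
    gene: str
    pair: tuple
    log2_fold_change: float
    p_value: float
    fdr: float
    direction: str  # up / down / unchanged (direction of B relative to A)


def call_de(
    counts: pd.DataFrame,
    pair: tuple,
    library_depths: pd.Series | dict | None = None,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE calls between two libraries (columns of ``counts``).

    Returns a DataFrame (gene, x, y, log2_fold_change, p_value, fdr,
    direction); direction is relative to library B.  FDR is computed across
    genes with at least one count in the pair; all-zero genes get p = fdr = 1.
    """
    lib_a, lib_b = pair
    for lib in pair:
        if lib not in counts.columns:
            raise ValueError(f"library {lib!r} not in count matrix")
    x = counts[lib_a].to_numpy()
    y = counts[lib_b].to_numpy()
    if library_depths is None:
        n1, n2 = float(x.sum()), float(y.sum())
    else:
        depths = pd.Series(library_depths, dtype=float)
        n1, n2 = float(depths[lib_a]), float(depths[lib_b])
    p = np.asarray(ac_test(x, n1, y, n2), dtype=float)
    tpm_a = x / n1 * 1e6
    tpm_b = y / n2 * 1e6
    lfc = np.log2((tpm_b + 1.0) / (tpm_a + 1.0))
    fdr = np.ones_like(p)
    observed = (x + y) >= 1
    if observed.any():
        fdr[observed] = multipletests(p[observed], method="fdr_bh")[1]
    direction = np.where(
        (fdr <= alpha) & (np.abs(lfc) >= lfc_min),
        np.where(lfc > 0, "up", "down"),
        "unchanged",
    )
    return pd.DataFrame(
        {
            "gene": counts.index,
            "x": x,
            "y": y,
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("gene")


@dataclass
class PatternCall:
    gene: str
    stage_directions: dict[str, str]
    pattern: str  # "S" or "D"


def classify_patterns(
    counts: pd.DataFrame,
    library_depths: pd.Series | dict,
    species: tuple[str, str],
    stages: tuple[str, ...] = STAGES,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """S/D expression-pattern classification across a gene x library matrix.

    Columns of ``counts`` (and keys of ``library_depths``) are
    (species, stage) tuples.  For each stage the two species are compared
    with :func:`call_de`; a gene is "D" iff any stage is significantly
    different, else "S".
    """
    sp_a, sp_b = species
    out = pd.DataFrame(index=counts.index)
    for stage in stages:
        de = call_de(
            counts, ((sp_a, stage), (sp_b, stage)), library_depths, alpha, lfc_min
        )
        out[stage] = de["direction"]
    out["pattern"] = np.where((out[list(stages)] != "unchanged").any(axis=1), "D", "S")
    return out


def classify_pattern(
    gene: str,
    counts_by_stage: dict[str, tuple[int, int]],
    depths_by_stage: dict[str, tuple[float, float]],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> PatternCall:
    """Single-gene convenience wrapper over :func:`classify_patterns`.

    ``counts_by_stage[stage] = (count_species_A, count_species_B)`` and
    likewise for depths.  With one gene the BH correction is the identity,
    so each stage's FDR equals its exact p-value.
    """
    stages = tuple(counts_by_stage)
    cols, depths = {}, {}
    for stage in stages:
        xa, xb = counts_by_stage[stage]
        na, nb = depths_by_stage[stage]
        cols[("A", stage)] = [xa]
        cols[("B", stage)] = [xb]
        depths[("A", stage)] = na
        depths[("B", stage)] = nb
    matrix = pd.DataFrame(cols, index=[gene])
    table = classify_patterns(matrix, depths, ("A", "B"), stages, alpha, lfc_min)
    row = table.loc[gene]
    return PatternCall(gene, {s: row[s] for s in stages}, row["pattern"])
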