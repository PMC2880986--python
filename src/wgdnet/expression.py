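"""Expression summaries per gene, enzyme aggregation and rank correlations.

Per gene the two summaries are the maximum intensity across conditions and
the expression-variation (tissue-specificity) index

    V = Σ_j (1 − S'_ij / S'_(i,max)) / (n − 1),   S'_ij = max(S_ij, floor)

with a default floor of 50 intensity units to damp noise at low signal.
V is 0 for a constant (floored) profile and approaches 1 for a gene
expressed in a single condition.  Gene summaries are averaged arithmetically
over the genes annotated to an enzyme.  Associations between centralities
and summaries use Spearman rank correlation with FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network_build import MetabolicNetwork
from .reaction_io import EnzymeGeneMap

__all__ = [
    "CorrelationResult",
    "load_expression_matrix",
    "variation_index",
    "summarize_genes",
    "aggregate_to_enzyme",
    "pearson_coexpression",
    "spearman_with_fdr",
    "divergence_screen",
]

DEFAULT_FLOOR = 50.0


@dataclass(frozen=True)
class CorrelationResult:
    label: str
    rho: float
    p_value: float
    q_value: float
    n: int


def load_expression_matrix(
    source, design: pd.DataFrame | Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Load a gene×condition intensity matrix from TSV (genes in rows).

    ``design`` optionally maps condition columns to replicate groups, which
    are averaged on load.  Intensities must be non-negative with ≥2
    conditions after averaging.
    """
    if isinstance(source, pd.DataFrame):
        matrix = source.copy()
    else:
        matrix = pd.read_csv(source, sep="\t", index_col=0)
    if design is not None:
        if isinstance(design, pd.DataFrame):
            groups = dict(zip(design.iloc[:, 0], design.iloc[:, 1]))
        else:
            groups = dict(design)
        matrix = matrix.T.groupby([groups[c] for c in matrix.columns]).mean().T
    if matrix.shape[1] < 2:
        raise ValueError("expression matrix needs >=2 conditions")
    if (matrix.to_numpy(dtype=float) < 0).any():
        raise ValueError("expression intensities must be non-negative")
    return matrix


def variation_index(profile: Sequence[float], floor: float = DEFAULT_FLOOR) -> float:
    """Expression-variation index V ∈ [0,1] of one intensity profile."""
    values = np.asarray(profile, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("variation index needs >=2 conditions")
    floored = np.maximum(values, floor)
    smax = floored.max()
    if smax == 0:
        return 0.0
    return float(np.sum(1.0 - floored / smax) / (n - 1))


def summarize_genes(
    matrix: pd.DataFrame, floor: float = DEFAULT_FLOOR
) -> pd.DataFrame:
    """Per-gene max intensity and variation index.

    Genes with missing values are excluded with a warning.  Returns a
    DataFrame indexed by gene with columns ``max_intensity``, ``variation``.
    """
    complete = matrix.dropna()
    dropped = len(matrix) - len(complete)
    if dropped:
        warnings.warn(f"excluded {dropped} genes with missing conditions", stacklevel=2)
    if complete.empty:
        return pd.DataFrame(columns=["max_intensity", "variation"])
    values = complete.to_numpy(dtype=float)
    floored = np.maximum(values, floor)
    smax = floored.max(axis=1)
    with np.errstate(invalid="ignore"):
        v = np.where(
            smax > 0,
            (1.0 - floored / smax[:, None]).sum(axis=1) / (values.shape[1] - 1),
            0.0,
        )
    return pd.DataFrame(
        {"max_intensity": values.max(axis=1), "variation": v}, index=complete.index
    )


def aggregate_to_enzyme(
    summaries: pd.DataFrame, enzyme_map: Mapping[str, EnzymeGeneMap]
) -> pd.DataFrame:
    """Arithmetic means of gene summaries over each enzyme's measured genes.

    Enzymes with no measured genes are omitted.  Columns:
    ``mean_max_intensity``, ``mean_variation``, ``n_genes``.
    """
    rows = []
    measured = set(summaries.index)
    for enz in sorted(enzyme_map):
        genes = sorted(enzyme_map[enz].gene_ids & measured)
        if not genes:
            continue
        sub = summaries.loc[genes]
        rows.append(
            {
                "enzyme_id": enz,
                "mean_max_intensity": float(sub["max_intensity"].mean()),
                "mean_variation": float(sub["variation"].mean()),
                "n_genes": len(genes),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["mean_max_intensity", "mean_variation", "n_genes"]
        )
    return pd.DataFrame(rows).set_index("enzyme_id")


def pearson_coexpression(
    profile_a: Sequence[float], profile_b: Sequence[float]
) -> float:
    """Product-moment correlation of two equal-length profiles (n ≥ 3).

    Returns NaN (with a warning) when either profile has zero variance.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if a.size < 3:
        raise ValueError("co-expression needs >=3 conditions")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance profile: co-expression undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def _storey_q(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed-lambda plug-in pi0 estimate."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pi0 * p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def spearman_with_fdr(
    pairs: Iterable[tuple[Sequence[float], Sequence[float], str]],
    method: str = "bh",
) -> list[CorrelationResult]:
    """Spearman rank correlations (average-rank ties, two-sided p) with FDR.

    Pairs with fewer than 5 matched finite observations are excluded with a
    warning.  ``method`` is ``"bh"`` (Benjamini-Hochberg, default) or
    ``"storey"``.
    """
    kept: list[tuple[str, float, float, int]] = []
    for x, y, label in pairs:
        xa = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
        mask = np.isfinite(xa) & np.isfinite(ya)
        if mask.sum() < 5:
            warnings.warn(f"pair {label!r}: n < 5, excluded", stacklevel=2)
            continue
        rho, p = stats.spearmanr(xa[mask], ya[mask])
        kept.append((label, float(rho), float(p), int(mask.sum())))
    if not kept:
        return []
    pvals = np.array([p for _, _, p, _ in kept])
    if method == "bh":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    elif method == "storey":
        qvals = _storey_q(pvals)
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return [
        CorrelationResult(label, rho, p, float(q), n)
        for (label, rho, p, n), q in zip(kept, qvals)
    ]


def divergence_screen(
    network: MetabolicNetwork,
    wgd_pairs: Iterable[tuple[str, str]],
    matrix: pd.DataFrame,
    theta_within: float = 0.0,
    theta_cross: float = 0.5,
) -> list[dict]:
    """Interacting enzyme pairs whose homeolog pairs diverged in concert.

    An edge is reported when each endpoint enzyme has a measured homeolog
    pair whose within-pair co-expression is below ``theta_within`` and the
    paralogs can be matched across the edge so that both matched cross-enzyme
    co-expressions exceed ``theta_cross``.
    """
    pairs_by_enzyme: dict[str, list[tuple[str, str]]] = {}
    measured = set(matrix.index)
    for g1, g2 in wgd_pairs:
        if g1 not in measured or g2 not in measured:
            continue
        for enz, rec in network.gene_map.items():
            if g1 in rec.gene_ids and g2 in rec.gene_ids:
                pairs_by_enzyme.setdefault(enz, []).append((g1, g2))

    def corr(u: str, v: str) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pearson_coexpression(matrix.loc[u], matrix.loc[v])

    hits: list[dict] = []
    for edge in network.edges:
        for pa in pairs_by_enzyme.get(edge.source, []):
            if not (c_a := corr(*pa)) < theta_within:
                continue
            for pb in pairs_by_enzyme.get(edge.target, []):
                if not (c_b := corr(*pb)) < theta_within:
                    continue
                for (x1, x2) in (pb, pb[::-1]):
                    c1, c2 = corr(pa[0], x1), corr(pa[1], x2)
                    if c1 > theta_cross and c2 > theta_cross:
                        hits.append(
                            {
                                "edge": edge.endpoints,
                                "pair_a": pa,
                                "pair_b": pb,
                                "within_a": c_a,
                                "within_b": c_b,
                                "cross": (c1, c2),
                            }
                        )
                        break
    return hits
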