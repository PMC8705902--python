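"""Metabolite-phenotype correlation statistics and the tri-partite network.

Net-secretion series of metabolites are tested against clinical time series
(BMI, leptin, adiponectin, the leptin/adiponectin ratio, ...) with Spearman
rank correlation; p-values are adjusted with the Benjamini-Hochberg false
discovery rate over the full pair family, and edges passing ``|rho| >
r_thresh`` and ``p_fdr < p_thresh`` (defaults 0.7 and 0.1) enter a network
together with the strains that produce the correlated metabolites.

The default two-sided p-value uses the t approximation ``t = rho *
sqrt((n-2)/(1-rho^2))`` on ``n-2`` degrees of freedom; an exact permutation
p-value (full enumeration, n <= 9) is available as ``method="exact"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pipeline import ContributionRecord

__all__ = [
    "ClinicalSeries",
    "CorrelationEdge",
    "SpearmanResult",
    "spearman",
    "fdr_bh",
    "correlate_features",
    "derived_ratio",
    "build_network",
    "RATIO_NAME",
]

logger = logging.getLogger(__name__)

RATIO_NAME = "leptin/adiponectin"


@dataclass
class ClinicalSeries:
    """Clinical parameters measured on a shared timepoint axis."""

    timepoints: list[str]
    parameters: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.timepoints)
        for name, series in self.parameters.items():
            if len(series) != n:
                raise ValueError(
                    f"clinical parameter {name!r} has {len(series)} values "
                    f"for {n} timepoints"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.parameters, index=self.timepoints)


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    #: True when |rho| = 1, where the t approximation degenerates and the
    #: p-value is reported as 0
    perfect: bool = False


@dataclass
class CorrelationEdge:
    feature_a: str  # metabolite
    feature_b: str  # clinical parameter
    rho: float
    p_raw: float
    p_fdr: float

    @property
    def sign(self) -> int:
        return 1 if self.rho >= 0 else -1


def _rank(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    ``method="t"`` uses the t approximation on n-2 degrees of freedom;
    ``method="exact"`` enumerates all n! permutations (n <= 9). Ties are
    handled by average ranks; for tie-free data rho equals
    ``1 - 6*sum(d^2)/(n*(n^2-1))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    rx, ry = _rank(x), _rank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("Spearman correlation undefined for a constant series")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rho) >= 1.0 - 1e-12:
            return SpearmanResult(rho=math.copysign(1.0, rho), p=0.0,
                                  perfect=True)
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
        return SpearmanResult(rho=rho, p=min(1.0, p))
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p-value supported for n <= 9")
        perms = np.array(list(permutations(ry)))
        rho_null = _pearson_against(rx, perms)
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p=p, perfect=abs(rho) >= 1.0 - 1e-12)
    raise ValueError(f"unknown method {method!r}")


def _pearson_against(rx: np.ndarray, perm_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``rx`` against each row, vectorised."""
    cx = rx - rx.mean()
    rows = perm_rows - perm_rows.mean(axis=1, keepdims=True)
    num = rows @ cx
    den = np.sqrt((rows ** 2).sum(axis=1) * (cx ** 2).sum())
    return num / den


def fdr_bh(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adjusted]


def derived_ratio(clinical: ClinicalSeries) -> np.ndarray:
    """Elementwise leptin / adiponectin series."""
    for name in ("leptin", "adiponectin"):
        if name not in clinical.parameters:
            raise KeyError(f"clinical series lacks {name!r}")
    lep = np.asarray(clinical.parameters["leptin"], dtype=float)
    adi = np.asarray(clinical.parameters["adiponectin"], dtype=float)
    for i, value in enumerate(adi):
        if value <= 0:
            raise ValueError(
                f"adiponectin is {value} at timepoint "
                f"{clinical.timepoints[i]!r}; ratio undefined"
            )
    return lep / adi


def correlate_features(
    metabolite_table: pd.DataFrame,
    clinical: ClinicalSeries,
    r_thresh: float = 0.7,
    p_thresh: float = 0.1,
    include_ratio: bool = True,
    method: str = "t",
) -> list[CorrelationEdge]:
    """Test every metabolite x clinical pair; FDR over the whole family.

    ``metabolite_table`` is samples x metabolites (net secretion series) on
    the same timepoint axis as ``clinical``. Constant features are skipped
    with a warning. Returned edges satisfy ``|rho| > r_thresh`` and
    ``p_fdr < p_thresh`` (strict), ordered by (metabolite, parameter).
    """
    timepoints = [str(t) for t in metabolite_table.index]
    if timepoints != [str(t) for t in clinical.timepoints]:
        raise ValueError(
            "metabolite table and clinical series disagree on the "
            f"timepoint axis: {timepoints} vs {clinical.timepoints}"
        )
    if len(timepoints) < 4:
        raise ValueError(
            f"need at least 4 shared timepoints, got {len(timepoints)}"
        )
    clin = {name: np.asarray(series, dtype=float)
            for name, series in sorted(clinical.parameters.items())}
    if include_ratio and {"leptin", "adiponectin"} <= set(clin):
        clin[RATIO_NAME] = derived_ratio(clinical)

    skipped = []
    pairs: list[tuple[str, str, float, float]] = []
    for met in sorted(metabolite_table.columns):
        mseries = metabolite_table[met].to_numpy(dtype=float)
        if np.ptp(mseries) == 0:
            skipped.append(met)
            continue
        for name in sorted(clin):
            cseries = clin[name]
            if np.ptp(cseries) == 0:
                skipped.append(name)
                continue
            res = spearman(mseries, cseries, method=method)
            pairs.append((met, name, res.rho, res.p))
    if skipped:
        logger.warning(
            "correlation: skipped constant features: %s",
            ", ".join(sorted(set(skipped))),
        )
    if not pairs:
        return []
    adjusted = fdr_bh([p for _, _, _, p in pairs])
    edges = [
        CorrelationEdge(met, name, rho, p_raw, p_fdr)
        for (met, name, rho, p_raw), p_fdr in zip(pairs, adjusted)
        if abs(rho) > r_thresh and p_fdr < p_thresh
    ]
    return edges


def build_network(
    edges: list[CorrelationEdge],
    contributions: list[ContributionRecord],
    focus: list[str] | None = None,
) -> nx.Graph:
    """Assemble the clinical-metabolite-strain network.

    Nodes carry a ``type`` attribute in {clinical, metabolite, strain};
    correlation edges carry sign/rho/p_fdr, production edges carry the
    summed share. Only metabolites with a retained correlation edge (to a
    focus parameter, when ``focus`` is given) appear, and only strains with
    positive share for those metabolites. Isolated nodes are dropped.
    """
    graph = nx.Graph()
    kept = [
        e for e in sorted(edges, key=lambda e: (e.feature_a, e.feature_b))
        if focus is None or e.feature_b in focus
    ]
    for edge in kept:
        graph.add_node(edge.feature_b, type="clinical")
        graph.add_node(edge.feature_a, type="metabolite")
        graph.add_edge(
            edge.feature_a, edge.feature_b,
            type="correlation", sign=edge.sign, rho=edge.rho,
            p_fdr=edge.p_fdr,
        )
    metabolites = {e.feature_a for e in kept}

    merged: dict[tuple[str, str], float] = {}
    seen: set[tuple[str, str]] = set()
    for rec in contributions:
        key = (rec.metabolite, rec.strain)
        if key in merged:
            if key not in seen:
                logger.warning(
                    "duplicate contribution records for %s/%s merged "
                    "(shares summed)", rec.metabolite, rec.strain,
                )
                seen.add(key)
            merged[key] += rec.share
        else:
            merged[key] = rec.share
    for (met, strain) in sorted(merged):
        share = merged[(met, strain)]
        if met in metabolites and share > 0:
            graph.add_node(strain, type="strain")
            graph.add_edge(met, strain, type="production", share=share)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph
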