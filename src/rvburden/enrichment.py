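"""Gene-set ("pathway burden") enrichment layer.

Mutated genes are scored against flat gene-set terms over a declared
background universe:

* fold enrichment = (k/n) / (K/N) for k hit genes among a list of n,
  against a term of K genes in a background of N;
* the EASE score, a deliberately conservative one-sided Fisher exact
  p-value in which one hit gene is discounted (the hypergeometric tail is
  evaluated at k-1 instead of k), so single-gene "enrichments" score 1.0;
* Benjamini-Hochberg adjustment across terms;
* kappa-similarity functional clustering: terms whose gene memberships
  agree beyond chance (Cohen's kappa over co-membership of the gene list)
  are grouped greedily and merged to a fixpoint, and each cluster gets an
  enrichment score, -log10 of the geometric mean of its members' EASE
  p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._exact import hypergeom_tail
from .io import GeneSetCollection, InputError

logger = logging.getLogger("rvburden")

__all__ = [
    "TermEnrichment",
    "TermCluster",
    "term_stats",
    "bh_adjust",
    "kappa_similarity",
    "cluster_terms",
    "TermEnrichmentAnalysis",
    "EnrichmentResults",
]


@dataclass(frozen=True)
class TermEnrichment:
    """Per-term enrichment statistics (q filled in by the analysis layer)."""

    term_id: str
    term_name: str
    k: int  # hit genes: |gene list ∩ term|
    n: int  # gene-list size counted against background
    K: int  # term size in background
    N: int  # background size
    fold: float
    p_ease: float
    hit_genes: frozenset[str]
    q: float | None = None


@dataclass(frozen=True)
class TermCluster:
    """A group of >= 2 functionally similar terms with a joint score."""

    cluster_id: int
    member_terms: tuple[str, ...]
    enrichment_score: float  # -log10(geometric mean of member p_ease)


def term_stats(
    gene_list,
    term_genes,
    background,
    term_id: str = "",
    term_name: str = "",
    method: str = "ease",
) -> TermEnrichment:
    """Enrichment statistics for one term.

    Genes outside the background are dropped with a warning and do not
    count toward the list size n.  ``method="ease"`` (default) applies the
    hit-minus-one discount; ``method="fisher"`` is the plain one-sided
    Fisher exact tail.
    """
    if method not in ("ease", "fisher"):
        raise ValueError(f"unknown enrichment method {method!r}")
    background = frozenset(background)
    term_genes = frozenset(term_genes) & background
    listed = frozenset(gene_list)
    stray = listed - background
    if stray:
        logger.warning(
            "%d gene(s) in list but not in background dropped (e.g. %s)",
            len(stray),
            sorted(stray)[:3],
        )
        listed = listed & background

    N, K, n = len(background), len(term_genes), len(listed)
    if K == 0:
        raise InputError(f"term {term_id or term_name} has no genes in background")
    if n == 0:
        raise InputError("gene list is empty after background restriction")
    hits = listed & term_genes
    k = len(hits)
    fold = (k / n) / (K / N)
    k_eff = max(k - 1, 0) if method == "ease" else k
    p = float(hypergeom_tail(n, N - n, K, k_eff))
    return TermEnrichment(
        term_id=term_id,
        term_name=term_name,
        k=k,
        n=n,
        K=K,
        N=N,
        fold=fold,
        p_ease=p,
        hit_genes=frozenset(hits),
    )


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clamped to 1; ties and the original order are preserved in the output.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def kappa_similarity(membership_a, membership_b) -> float:
    """Cohen's kappa between two boolean membership vectors.

    Both vectors must cover the same ordered gene universe.  Returns the
    chance-corrected agreement (Po - Pe) / (1 - Pe); when the expected
    agreement Pe is 1 (both vectors constant and equal-rate) the kappa is
    defined as 0.
    """
    a = np.asarray(membership_a, dtype=bool)
    b = np.asarray(membership_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("membership vectors must be 1-d and equal length")
    n = a.size
    if n == 0:
        raise InputError("gene universe must be non-empty")
    both = int((a & b).sum())
    neither = int((~a & ~b).sum())
    po = (both + neither) / n
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 0.0
    return float((po - pe) / (1 - pe))


def _geomean_score(pvals) -> float:
    return float(-np.mean([math.log10(p) for p in pvals]))


def cluster_terms(
    enrichments: list[TermEnrichment],
    universe,
    kappa_threshold: float = 0.35,
    seed_min_size: int = 3,
    merge_overlap: float = 0.5,
) -> list[TermCluster]:
    """Greedy fuzzy clustering of terms by kappa similarity of their hit
    genes over the supplied gene universe.

    For each term a candidate group collects every term with kappa >=
    ``kappa_threshold`` to it (itself included); groups below
    ``seed_min_size`` are discarded; any two groups sharing at least
    ``merge_overlap`` of the smaller group's members are merged, repeating
    to a fixpoint.  Terms are processed in lexicographic term_id order so
    the outcome is deterministic.  Each cluster's enrichment score is
    -log10 of the geometric mean of member EASE p-values; clusters are
    returned sorted by score descending.
    """
    universe = sorted(set(universe))
    if not universe:
        raise InputError("clustering universe must be non-empty")
    idx = {g: i for i, g in enumerate(universe)}
    by_id = {e.term_id: e for e in enrichments}
    term_ids = sorted(by_id)
    vectors = {}
    for tid in term_ids:
        v = np.zeros(len(universe), dtype=bool)
        for g in by_id[tid].hit_genes:
            if g in idx:
                v[idx[g]] = True
        vectors[tid] = v

    # (i) seed groups, (ii) size filter
    groups: list[frozenset[str]] = []
    for tid in term_ids:
        members = frozenset(
            other
            for other in term_ids
            if other == tid
            or kappa_similarity(vectors[tid], vectors[other]) >= kappa_threshold
        )
        if len(members) >= seed_min_size:
            groups.append(members)
    groups = sorted(set(groups), key=lambda g: sorted(g))

    # (iii) merge to fixpoint; each merge strictly reduces the group count
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                small = min(len(groups[i]), len(groups[j]))
                if len(groups[i] & groups[j]) >= merge_overlap * small:
                    union = groups[i] | groups[j]
                    groups = (
                        groups[:i] + groups[i + 1 : j] + groups[j + 1 :] + [union]
                    )
                    groups.sort(key=lambda g: sorted(g))
                    merged = True
                    break
            if merged:
                break

    clusters = []
    for members in groups:
        if len(members) < 2:
            continue
        score = _geomean_score([by_id[t].p_ease for t in members])
        clusters.append((score, tuple(sorted(members))))
    clusters.sort(key=lambda sc: (-sc[0], sc[1]))
    return [
        TermCluster(cluster_id=i + 1, member_terms=members, enrichment_score=score)
        for i, (score, members) in enumerate(clusters)
    ]


# ---------------------------------------------------------------------------
# Model / Results objects


class TermEnrichmentAnalysis:
    """Gene-set enrichment of a mutated-gene list against a collection.

    The background defaults to the collection's full gene universe; the
    test per term is the EASE score (``method="fisher"`` switches to the
    plain Fisher tail).  ``fit`` returns an :class:`EnrichmentResults`.
    """

    def __init__(
        self,
        gene_list,
        gene_sets: GeneSetCollection,
        method: str = "ease",
    ):
        self.gene_list = sorted(set(gene_list))
        if not self.gene_list:
            raise InputError("gene list must be non-empty")
        self.gene_sets = gene_sets
        self.method = method

    def fit(self) -> "EnrichmentResults":
        enrichments = []
        for term_id in sorted(self.gene_sets.terms):
            name, genes = self.gene_sets.terms[term_id]
            enrichments.append(
                term_stats(
                    self.gene_list,
                    genes,
                    self.gene_sets.background,
                    term_id=term_id,
                    term_name=name,
                    method=self.method,
                )
            )
        qs = bh_adjust([e.p_ease for e in enrichments])
        enrichments = [replace(e, q=q) for e, q in zip(enrichments, qs)]
        enrichments.sort(key=lambda e: (e.p_ease, e.term_id))
        return EnrichmentResults(self, enrichments)


class EnrichmentResults:
    """Per-term enrichment results, sorted ascending by EASE p."""

    def __init__(self, model: TermEnrichmentAnalysis, terms: list[TermEnrichment]):
        self.model = model
        self.terms = terms

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "TERM_ID": [e.term_id for e in self.terms],
                "TERM_NAME": [e.term_name for e in self.terms],
                "K_HITS": [e.k for e in self.terms],
                "N_LIST": [e.n for e in self.terms],
                "K_TERM": [e.K for e in self.terms],
                "N_BG": [e.N for e in self.terms],
                "FOLD": [e.fold for e in self.terms],
                "P_EASE": [e.p_ease for e in self.terms],
                "Q": [e.q for e in self.terms],
            }
        )

    def cluster(
        self,
        kappa_threshold: float = 0.35,
        seed_min_size: int = 3,
        merge_overlap: float = 0.5,
    ) -> list[TermCluster]:
        """Kappa-similarity clustering over the analysed gene list."""
        listed = set(self.model.gene_list) & set(self.model.gene_sets.background)
        return cluster_terms(
            self.terms,
            universe=listed,
            kappa_threshold=kappa_threshold,
            seed_min_size=seed_min_size,
            merge_overlap=merge_overlap,
        )

    def cluster_frame(self, clusters: list[TermCluster]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "CLUSTER_ID": [c.cluster_id for c in clusters],
                "SCORE": [c.enrichment_score for c in clusters],
                "MEMBER_TERMS": [",".join(c.member_terms) for c in clusters],
            }
        )

    def summary(self, max_rows: int = 15) -> str:
        df = self.frame.copy()
        df["FOLD"] = df["FOLD"].map(lambda x: f"{x:.2f}")
        df["P_EASE"] = df["P_EASE"].map(lambda x: f"{x:.3g}")
        df["Q"] = df["Q"].map(lambda x: f"{x:.3g}")
        lines = [
            f"Gene-set enrichment ({self.model.method.upper()} score), "
            f"{len(df)} terms, list n={self.terms[0].n if self.terms else 0}, "
            f"background N={len(self.model.gene_sets.background)}",
            df.head(max_rows).to_string(index=False),
        ]
        return "\n".join(lines)
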