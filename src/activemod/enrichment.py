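"""Annotation-term over-representation for detected modules.

Flat Fisher's exact test (one-sided, enrichment direction — equivalently the
hypergeometric upper tail) per term, with Benjamini–Hochberg correction
across all tested terms. Any gene→term mapping works: GO slims, pathway
collections, hand-made sets. No ontology topology is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, ValidationError
from .module_detection import SteinerModule

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Term → gene-set mapping restricted to a gene universe.

    The universe defaults, at test time, to all genes that carried a p-value
    in the run, so that the background reflects what could have entered a
    module at all.
    """

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def restricted(self, universe: set[str]) -> "AnnotationMap":
        """Intersect every term's gene set with ``universe``; drop empties."""
        out = {}
        n_dropped = 0
        for term, genes in self.terms.items():
            g = genes & universe
            if g:
                out[term] = g
            else:
                n_dropped += 1
        if n_dropped:
            logger.info("skipped %d term(s) with no genes in the universe", n_dropped)
        return AnnotationMap(terms=out, universe=set(universe))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome.

    ``fold_label`` is the ``k/K`` pair: module genes carrying the term over
    universe genes carrying it.
    """

    term: str
    k: int
    K: int
    M: int
    N: int
    p_raw: float
    p_adjusted: float
    significant: bool

    @property
    def fold_label(self) -> str:
        return f"{self.k}/{self.K}"


def read_gmt(path: str | Path) -> AnnotationMap:
    """Read a GMT file: one term per line, tab-separated, description in
    column 2, member genes from column 3 on."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            terms[parts[0]] = set(parts[2:])
    return AnnotationMap(terms=terms)


def read_gene_term_tsv(path: str | Path) -> AnnotationMap:
    """Read a two-column (gene, term) TSV into an annotation map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    if df.isna().any().any():
        raise FormatError(f"{path}: expected exactly two tab-separated columns")
    terms: dict[str, set[str]] = {}
    for term, grp in df.groupby("term"):
        terms[str(term)] = set(grp["gene"])
    return AnnotationMap(terms=terms)


def _bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def enrich(
    module: SteinerModule | set[str],
    annot: AnnotationMap,
    universe: set[str] | None = None,
    alpha_sig: float = 0.01,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in the module.

    Parameters
    ----------
    module
        A detected module (its node set is used) or a plain gene set.
    annot
        Term → gene-set mapping; restricted to the universe before testing.
    universe
        Background gene set. Defaults to ``annot.universe``.
    alpha_sig
        Adjusted-p cutoff for the ``significant`` flag.

    Returns
    -------
    Results sorted by ascending adjusted p (ties by raw p, then term),
    one per term with at least one universe gene.
    """
    genes = module.nodes if isinstance(module, SteinerModule) else set(module)
    uni = set(universe) if universe is not None else set(annot.universe)
    if not uni:
        raise ValidationError("empty gene universe")
    if not genes:
        raise ValidationError("empty module")
    genes = genes & uni
    restricted = annot.restricted(uni)
    N, M = len(uni), len(genes)

    results = []
    raw = []
    for term in sorted(restricted.terms):
        members = restricted.terms[term]
        K = len(members)
        k = len(members & genes)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, M)
        p = float(hypergeom.sf(k - 1, N, K, M))
        raw.append(p)
        results.append((term, k, K, p))
    adj = _bh_adjust(raw)
    out = [
        EnrichmentResult(
            term=term,
            k=k,
            K=K,
            M=M,
            N=N,
            p_raw=p,
            p_adjusted=min(a, 1.0),
            significant=a < alpha_sig,
        )
        for (term, k, K, p), a in zip(results, adj)
    ]
    out.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return out


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results, including the ``k/K`` fold label."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "fold": [r.fold_label for r in results],
            "module_size": [r.M for r in results],
            "universe_size": [r.N for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )
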