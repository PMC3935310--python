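"""Compartment co-localization network by fixed-margin permutation testing.

Protein-compartment links with more than two stars (disregarding weak
text-mining and prediction evidence) form a bipartite membership.  For every
pair of compartments the observed number of shared proteins is compared to a
null in which the compartment endpoints of the link list are permuted,
preserving the number of links per protein and per compartment exactly.
Empirical p-values (fraction of permutations with a shared count at least as
large as observed) are corrected by Benjamini-Hochberg at a 0.1% FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .unify import UnifiedTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_STARS = 2.0
DEFAULT_FDR = 0.001
DEFAULT_N_PERM = 10_000


@dataclass
class LinkSet:
    """Deduplicated (protein, compartment) links surviving the star filter."""

    links: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.links)) != len(self.links):
            raise ValidationError("duplicate links in LinkSet")
        self.protein_degree: dict[str, int] = {}
        self.term_degree: dict[str, int] = {}
        for protein, term in self.links:
            self.protein_degree[protein] = self.protein_degree.get(protein, 0) + 1
            self.term_degree[term] = self.term_degree.get(term, 0) + 1

    def __len__(self) -> int:
        return len(self.links)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_degree)


def filter_links(table: UnifiedTable, min_stars_exclusive: float = DEFAULT_MIN_STARS) -> LinkSet:
    """Keep links whose overall stars are strictly above the threshold."""
    links = sorted(
        (protein, term)
        for (protein, term), channels in table.cells.items()
        if max(channels.values()) > min_stars_exclusive
    )
    return LinkSet(links=links)


def shared_counts(links: LinkSet) -> dict[tuple[str, str], int]:
    """Observed shared-protein count for every unordered compartment pair."""
    member: dict[str, set[str]] = {}
    for protein, term in links.links:
        member.setdefault(term, set()).add(protein)
    counts: dict[tuple[str, str], int] = {}
    for a, b in combinations(sorted(member), 2):
        counts[(a, b)] = len(member[a] & member[b])
    return counts


def permute_null(
    links: LinkSet, n_perm: int, seed: int
) -> dict[tuple[str, str], np.ndarray]:
    """Null shared-count samples under endpoint-label permutation.

    Each replicate shuffles the compartment column of the link list, which
    preserves both the per-protein and per-compartment link counts exactly.
    Duplicate (protein, term) links arising in a replicate collapse for
    counting, matching the set semantics of "proteins shared".
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    proteins = sorted(links.protein_degree)
    terms = links.terms
    p_index = {p: i for i, p in enumerate(proteins)}
    t_index = {t: i for i, t in enumerate(terms)}
    p_idx = np.array([p_index[p] for p, _ in links.links], dtype=np.intp)
    t_idx = np.array([t_index[t] for _, t in links.links], dtype=np.intp)

    rng = np.random.default_rng(seed)
    n_terms = len(terms)
    membership = np.zeros((len(proteins), n_terms), dtype=np.float32)
    null = np.empty((n_perm, n_terms, n_terms), dtype=np.int32)
    for r in range(n_perm):
        permuted = rng.permutation(t_idx)
        membership[:] = 0.0
        membership[p_idx, permuted] = 1.0  # duplicates collapse here
        null[r] = (membership.T @ membership).astype(np.int32)
    return {
        (a, b): null[:, t_index[a], t_index[b]].copy()
        for a, b in combinations(terms, 2)
    }


def empirical_p(observed: int, null_samples: Sequence[int] | np.ndarray) -> float:
    """p = #{null >= observed} / n, floored at 1/n so BH never sees zero."""
    arr = np.asarray(null_samples)
    if arr.size == 0:
        raise ValidationError("empirical_p requires at least one null sample")
    count = int((arr >= observed).sum())
    if count == 0:
        logger.info("observed count exceeds all %d null samples: p floored", arr.size)
        return 1.0 / arr.size
    return count / arr.size


def bh_significant(
    pvalues: Mapping[tuple[str, str], float], q: float = DEFAULT_FDR
) -> set[tuple[str, str]]:
    """Benjamini-Hochberg step-up at level q over all tested pairs."""
    if not (0.0 < q < 1.0):
        raise ValidationError("q must lie in (0, 1)")
    if not pvalues:
        return set()
    pairs = list(pvalues)
    reject, _, _, _ = multipletests(
        [pvalues[p] for p in pairs], alpha=q, method="fdr_bh"
    )
    return {pair for pair, rej in zip(pairs, reject) if rej}


@dataclass(frozen=True)
class CompartmentLink:
    """A tested compartment pair with shared count, p-value and FDR call."""

    term_a: str
    term_b: str
    shared: int
    p: float
    significant: bool


def coloc_network(
    links: LinkSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    q: float = DEFAULT_FDR,
) -> list[CompartmentLink]:
    """Full test: observed counts, permutation null, empirical p, BH calls."""
    observed = shared_counts(links)
    null = permute_null(links, n_perm=n_perm, seed=seed)
    pvalues = {pair: empirical_p(observed[pair], null[pair]) for pair in observed}
    significant = bh_significant(pvalues, q=q)
    return [
        CompartmentLink(
            term_a=a,
            term_b=b,
            shared=observed[(a, b)],
            p=pvalues[(a, b)],
            significant=(a, b) in significant,
        )
        for a, b in sorted(observed)
    ]


def write_network_tsv(network: Iterable[CompartmentLink], path: str | Path) -> None:
    """Edge table: term_a, term_b, shared, p, significant."""
    with open(path, "w", newline="\n") as fh:
        fh.write("term_a\tterm_b\tshared\tp\tsignificant\n")
        for link in sorted(network, key=lambda l: (l.term_a, l.term_b)):
            fh.write(
                f"{link.term_a}\t{link.term_b}\t{link.shared}\t{link.p:.6g}\t"
                f"{str(link.significant).lower()}\n"
            )
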