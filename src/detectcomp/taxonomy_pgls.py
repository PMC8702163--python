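"""Taxonomy-based surrogate phylogeny and phylogenetic least squares.

When no molecular phylogeny is available, a tree built from nested taxonomic
ranks (order / family / genus / species) with every branch length set to 1
serves as a surrogate. Under Brownian-motion evolution the covariance between
two tips equals their shared root-to-tip path length, so with four unit-length
levels the variance-covariance matrix has diagonal 4 and off-diagonals
3 / 2 / 1 / 0 for pairs sharing a genus / family / order / nothing.

The relationship between phylogeny and the regression residuals is quantified
with an intercept-only generalized least squares fit: the GLS mean of the
residuals under the Brownian covariance, with a t test against zero.

Several populations may belong to the same species; identical rows would make
the covariance matrix singular, so repeated species receive an off-diagonal
of 4 - epsilon (a small independent within-species component, epsilon
configurable, 1e-6 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import linalg as sla
from scipy import stats

from .errors import (
    DomainError,
    InconsistentTaxonomyError,
    SingularCovarianceError,
)

LEVELS = ("order", "family", "genus", "species")


def _tip_label(species: str) -> str:
    return species.strip().replace(" ", "_")


@dataclass(frozen=True)
class TaxonTree:
    """Four-level taxonomy tree with unit branch lengths.

    ``taxonomy`` maps each species to its (order, family, genus, species)
    tuple; ``tree`` is the dendropy representation used for Newick I/O. Every
    tip sits at depth exactly 4 from the root.
    """

    tree: dendropy.Tree
    taxonomy: dict

    @property
    def tips(self) -> list[str]:
        return sorted(self.taxonomy)

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "TaxonTree":
        """Rebuild a TaxonTree from its Newick serialization.

        Taxonomy labels are recovered from the internal-node labels written
        by :func:`build_taxonomy_tree`.
        """
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        taxonomy = {}
        for leaf in tree.leaf_node_iter():
            species = leaf.taxon.label.replace("_", " ")
            lineage = []
            node = leaf.parent_node
            while node is not None and node.parent_node is not None:
                lineage.append(node.label or "")
                node = node.parent_node
            lineage.reverse()  # order, family, genus
            taxonomy[species] = tuple(lineage[-3:]) + (species,)
        return cls(tree=tree, taxonomy=taxonomy)

    def shared_depths(self) -> tuple[list[str], np.ndarray]:
        """Tip labels and the matrix of shared root-to-tip path lengths.

        Computed from the tree itself: entry (i, j) is the depth of the most
        recent common ancestor of tips i and j (diagonal: tip depth, 4).
        """
        leaves = sorted(self.tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        labels = [l.taxon.label.replace("_", " ") for l in leaves]
        # ancestor chains with depths, root depth 0
        chains = []
        for leaf in leaves:
            chain = {}
            node, depth = leaf, 0.0
            edges = []
            while node is not None:
                edges.append(node)
                node = node.parent_node
            total = len(edges) - 1  # number of edges to root (unit lengths)
            for d, nd in enumerate(reversed(edges)):
                chain[id(nd)] = float(d)
            chains.append((chain, float(total)))
        n = len(leaves)
        out = np.zeros((n, n))
        for i in range(n):
            out[i, i] = chains[i][1]
            for j in range(i + 1, n):
                shared = max(
                    (d for nid, d in chains[i][0].items() if nid in chains[j][0]),
                    default=0.0,
                )
                out[i, j] = out[j, i] = shared
        return labels, out


def build_taxonomy_tree(records: Iterable) -> TaxonTree:
    """Build the unit-branch-length taxonomy tree from taxonomy rows.

    ``records`` may be anything with ``order``, ``family``, ``genus``,
    ``species`` attributes (e.g. study-table records) or 4-tuples in that
    order. Duplicate species collapse to a single tip; a species assigned to
    two different higher taxa across rows raises
    :class:`InconsistentTaxonomyError`.
    """
    taxonomy: dict[str, tuple[str, str, str, str]] = {}
    for rec in records:
        if isinstance(rec, (tuple, list)):
            order, family, genus, species = (str(v).strip() for v in rec[:4])
        else:
            order, family, genus, species = (
                str(getattr(rec, lvl)).strip() for lvl in LEVELS
            )
        if not all((order, family, genus, species)):
            raise DomainError(f"empty taxonomy level in row for species {species!r}")
        row = (order, family, genus, species)
        if species in taxonomy and taxonomy[species] != row:
            raise InconsistentTaxonomyError(
                f"species {species!r} assigned to both {taxonomy[species][:3]}"
                f" and {row[:3]}"
            )
        taxonomy[species] = row
    if not taxonomy:
        raise DomainError("no taxonomy rows supplied")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # nested order -> family -> genus nodes, species as leaves
    order_nodes: dict[str, dendropy.Node] = {}
    family_nodes: dict[tuple, dendropy.Node] = {}
    genus_nodes: dict[tuple, dendropy.Node] = {}
    for species in sorted(taxonomy):
        order, family, genus, _ = taxonomy[species]
        if order not in order_nodes:
            nd = tree.seed_node.new_child(edge_length=1.0)
            nd.label = order
            order_nodes[order] = nd
        if (order, family) not in family_nodes:
            nd = order_nodes[order].new_child(edge_length=1.0)
            nd.label = family
            family_nodes[(order, family)] = nd
        if (order, family, genus) not in genus_nodes:
            nd = family_nodes[(order, family)].new_child(edge_length=1.0)
            nd.label = genus
            genus_nodes[(order, family, genus)] = nd
        leaf = genus_nodes[(order, family, genus)].new_child(edge_length=1.0)
        leaf.taxon = taxa.new_taxon(label=_tip_label(species))
    return TaxonTree(tree=tree, taxonomy=dict(taxonomy))


def brownian_vcv(
    tree: TaxonTree,
    row_species: Sequence[str],
    epsilon: float = 1e-6,
) -> np.ndarray:
    """Brownian variance-covariance matrix for one row per population.

    Entry (i, j) is the shared root-to-tip path length of the species of
    rows i and j; the diagonal is 4. Distinct populations of the same species
    get 4 - ``epsilon`` off-diagonal so the matrix stays positive definite.
    """
    if epsilon < 0:
        raise DomainError(f"epsilon must be nonnegative, got {epsilon!r}")
    labels, tipvcv = tree.shared_depths()
    index = {sp: i for i, sp in enumerate(labels)}
    missing = [sp for sp in row_species if sp not in index]
    if missing:
        raise DomainError(f"species not in tree: {sorted(set(missing))}")
    n = len(row_species)
    V = np.empty((n, n))
    for i, si in enumerate(row_species):
        for j, sj in enumerate(row_species):
            if i == j:
                V[i, j] = tipvcv[index[si], index[si]]
            elif si == sj:
                V[i, j] = tipvcv[index[si], index[si]] - epsilon
            else:
                V[i, j] = tipvcv[index[si], index[sj]]
    return V


@dataclass(frozen=True)
class PGLSResult:
    intercept: float
    se: float
    sigma2: float
    t_stat: float
    df: int
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "se": self.se,
            "sigma2": self.sigma2,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "n": self.n,
        }


def pgls_intercept(y, V) -> PGLSResult:
    """Intercept-only generalized least squares under covariance ``V``.

    intercept = (1' V^-1 1)^-1 1' V^-1 y;
    sigma2 = (y - mu)' V^-1 (y - mu) / (n - 1);
    se = sqrt(sigma2 / (1' V^-1 1)); two-sided t test on n - 1 df.

    When ``V`` is (a multiple of) the identity this reduces exactly to the
    arithmetic mean and its standard error.
    """
    y = np.asarray(y, dtype=float)
    V = np.asarray(V, dtype=float)
    n = y.size
    if V.shape != (n, n):
        raise DomainError(f"V must be {n}x{n} to match y, got {V.shape}")
    try:
        cho = sla.cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "covariance matrix is not positive definite; with repeated species"
            " use a positive within-species epsilon"
        ) from exc
    ones = np.ones(n)
    Vinv_1 = sla.cho_solve(cho, ones)
    Vinv_y = sla.cho_solve(cho, y)
    denom = float(ones @ Vinv_1)
    mu = float(ones @ Vinv_y) / denom
    r = y - mu
    sigma2 = float(r @ sla.cho_solve(cho, r)) / (n - 1)
    se = math.sqrt(sigma2 / denom)
    t = mu / se if se > 0 else math.inf
    p = float(2 * stats.t.sf(abs(t), n - 1)) if math.isfinite(t) else 0.0
    return PGLSResult(
        intercept=mu, se=se, sigma2=sigma2, t_stat=t, df=n - 1, p_value=p, n=n
    )
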