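"""Ortholog selection from a gene tree containing paralogs.

After a gene duplication, a family tree splits into paralogous clades
(e.g. Dicer1 vs. Dicer2). Variant interpretation must be based on true
orthologs of the reference, so this module extracts the largest clade
that contains the reference sequence and excludes designated paralog
exemplars, optionally requiring branch support and optionally dropping
sequences from species that still carry the paralog.
"""

from __future__ import annotations

import io
import logging
import warnings

import dendropy

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


def read_newick(stream) -> dendropy.Tree:
    """Parse a Newick gene tree; internal node labels may carry support values.

    Leaf labels must be unique (they are matched against sequence ids).
    Underscores in labels are kept verbatim, not turned into spaces.
    """
    if not isinstance(stream, str):
        stream = stream.read()
    try:
        tree = dendropy.Tree.get(
            data=stream,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise TreeError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _node_support(node: dendropy.Node) -> float | None:
    lbl = node.label
    if lbl is None:
        return None
    try:
        return float(lbl)
    except ValueError:
        return None


def select_ortholog_clade(
    tree: dendropy.Tree,
    ref_leaf: str,
    paralog_leaves: set[str],
    min_support: float | None = None,
) -> set[str]:
    """Leaf ids of the largest clade containing the reference and no paralog.

    The tree is first rerooted on the edge above the paralog exemplars'
    common ancestor, treating the paralogs as the outgroup. We then ascend
    from the reference leaf: the highest ancestor whose subtree is free of
    paralog leaves (and, if ``min_support`` is set, whose subtending branch
    support reaches it) defines the selection. Nodes without a support
    label are treated as qualifying. If only the reference itself
    qualifies, a warning is issued and the singleton set returned.
    """
    labels = leaf_labels(tree)
    if ref_leaf not in labels:
        raise TreeError(f"reference leaf {ref_leaf!r} not in tree")
    paralog_leaves = set(paralog_leaves)
    if not paralog_leaves:
        raise TreeError("paralog exemplar set must be non-empty")
    if ref_leaf in paralog_leaves:
        raise TreeError("reference leaf cannot be a paralog exemplar")
    missing = paralog_leaves - labels
    if missing:
        raise TreeError(f"paralog leaves not in tree: {sorted(missing)}")

    tree = tree.clone(depth=1)
    taxa = tree.taxon_namespace

    # root with the paralogs as outgroup: reroot near the reference first so
    # the paralog MRCA is a proper node, then put the root on its edge
    ref_node = tree.find_node_with_taxon_label(ref_leaf)
    tree.reroot_at_edge(ref_node.edge, update_bipartitions=False)
    mrca = tree.mrca(taxa=[taxa.get_taxon(l) for l in paralog_leaves])
    if mrca is not tree.seed_node:
        tree.reroot_at_edge(mrca.edge, update_bipartitions=False)

    ref_node = tree.find_node_with_taxon_label(ref_leaf)
    best: set[str] = {ref_leaf}
    node = ref_node.parent_node
    while node is not None:
        clade = {leaf.taxon.label for leaf in node.leaf_iter()}
        if clade & paralog_leaves:
            break
        support = _node_support(node)
        if min_support is None or support is None or support >= min_support:
            best = clade
        node = node.parent_node
    if best == {ref_leaf}:
        warnings.warn(
            f"only the trivial clade of {ref_leaf!r} excludes all paralogs",
            stacklevel=2,
        )
    return best


def exclude_species_with_paralog(
    ids: set[str],
    species_of: dict[str, str],
    paralog_species: set[str],
) -> set[str]:
    """Drop ids whose species also possesses the paralog.

    In lineages retaining both copies, the ortholog's function may not have
    broadened, so those sequences are excluded from the evidence set.
    """
    missing = [i for i in ids if i not in species_of]
    if missing:
        raise TreeError(f"no species mapping for: {sorted(missing)}")
    kept = set()
    for i in sorted(ids):
        if species_of[i] in paralog_species:
            logger.info("excluding %s: species %s carries the paralog", i, species_of[i])
        else:
            kept.add(i)
    return kept


def read_species_map(stream) -> dict[str, str]:
    """Read an id<TAB>species table (no header) into a dict."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TreeError(f"bad species-map line: {line!r}")
        out[parts[0]] = parts[1]
    return out
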