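"""FASTA / Newick / report I/O.

FASTA reading goes through Biopython; Newick through dendropy.  Alignments
are uppercased, RNA is mapped to DNA (U -> T), and non-IUPAC characters are
rejected.  Trees must be rooted (binary at the base); a basal multifurcation
is rejected unless a rooting instruction is given.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import dendropy
from Bio import SeqIO

from .alignment import Alignment, AlignmentError
from .likelihood import ModelFit
from .models import NREV12_RATE_ORDER, Family
from .trees import RootedTree, TreeError

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "fit_report",
    "write_fit_report",
]

log = logging.getLogger("nrevphylo")


def read_alignment(path: str | Path) -> Alignment:
    """Read and validate a FASTA alignment (wrapped or single-line)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty or not FASTA")
    names = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        offender = next(r.id for r in records if len(r.seq) != len(seqs[0]))
        raise AlignmentError(
            f"{path}: ragged alignment (record {offender!r} has a different length)"
        )
    for name, seq in zip(names, seqs):
        if "*" in seq or "." in seq:
            raise AlignmentError(f"{path}: record {name!r} contains '*' or '.'")
    try:
        return Alignment(tuple(names), tuple(seqs))
    except AlignmentError as exc:
        raise AlignmentError(f"{path}: {exc}") from None


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{name}\n{seq}\n")


def read_tree(
    path: str | Path,
    root_on: str | None = None,
    missing_lengths: str = "error",
) -> RootedTree:
    """Read a rooted Newick tree with branch lengths.

    A basal trifurcation (unrooted convention) is rejected unless
    ``root_on`` names a leaf taxon or is ``"midpoint"``; the applied rooting
    is logged.  ``missing_lengths`` is ``"error"`` or ``"zero"``.
    """
    path = Path(path)
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"{path}: unreadable Newick ({exc})") from None

    internal_labels = [
        nd.label for nd in dtree.preorder_node_iter()
        if nd.label and not nd.is_leaf()
    ]
    if internal_labels:
        log.warning("%s: ignoring internal node labels %s", path, internal_labels[:3])

    missing = [
        e for e in dtree.preorder_edge_iter()
        if e.length is None and e.head_node is not dtree.seed_node
    ]
    if missing:
        if missing_lengths == "error":
            raise TreeError(f"{path}: {len(missing)} branch length(s) missing")
        for e in missing:
            e.length = 0.0

    n_basal = len(dtree.seed_node.child_nodes())
    if n_basal > 2:
        if root_on is None:
            raise TreeError(
                f"{path}: basal {n_basal}-furcation; pass root_on=<taxon|midpoint>"
            )
        if root_on == "midpoint":
            dtree.reroot_at_midpoint(update_bipartitions=False)
            log.info("%s: rooted at midpoint", path)
        else:
            taxon = dtree.taxon_namespace.get_taxon(root_on)
            if taxon is None:
                raise TreeError(f"{path}: taxon {root_on!r} not in tree")
            leaf = dtree.find_node_for_taxon(taxon)
            length = leaf.edge.length or 0.0
            dtree.reroot_at_edge(leaf.edge, length1=length / 2, length2=length / 2,
                                 update_bipartitions=False)
            log.info("%s: rooted on edge of %r", path, root_on)

    tree = RootedTree.from_dendropy(dtree)
    tree.validate()
    return tree


def write_tree(tree: RootedTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def fit_report(fit: ModelFit) -> dict:
    """Keyed report of a model fit (JSON-serializable)."""
    report = {
        "family": fit.family.value,
        "log_likelihood": fit.log_likelihood,
        "k": fit.k,
        "n_sites": fit.n_sites,
        "converged": fit.converged,
        "gamma_shape": fit.gamma_shape,
        "frequencies": {n: fit.frequencies[n] for n in "ACGT"},
        "root_frequencies": {n: fit.root_frequencies[n] for n in "ACGT"},
    }
    if fit.family is Family.GTR:
        report["rates"] = {f"{x}-{y}": v for (x, y), v in fit.rates.items()}
    else:
        report["rates"] = {
            f"{x}-{y}": fit.rates[(x, y)] for x, y in NREV12_RATE_ORDER
        }
    return report


def write_fit_report(fit: ModelFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_report(fit), indent=2) + "\n")
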