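"""Nucleotide alignment container.

Sequences are stored as uppercase strings over A, C, G, T, '-' and the IUPAC
ambiguity codes.  Gaps and ambiguity codes are treated as (partially) missing
data: each symbol maps to the set of compatible states, which the likelihood
engine turns into a 0/1 partial vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import NUCLEOTIDES

__all__ = ["Alignment", "AlignmentError", "AMBIGUITY"]


class AlignmentError(ValueError):
    pass


#: IUPAC nucleotide codes -> compatible states.  Gap and N are fully missing.
AMBIGUITY: dict[str, tuple[str, ...]] = {
    "A": ("A",), "C": ("C",), "G": ("G",), "T": ("T",),
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"), "W": ("A", "T"),
    "K": ("G", "T"), "M": ("A", "C"),
    "B": ("C", "G", "T"), "D": ("A", "G", "T"),
    "H": ("A", "C", "T"), "V": ("A", "C", "G"),
    "N": NUCLEOTIDES, "-": NUCLEOTIDES, "?": NUCLEOTIDES,
}

_STATE_VECTORS = {
    sym: np.array([1.0 if n in states else 0.0 for n in NUCLEOTIDES])
    for sym, states in AMBIGUITY.items()
}

# integer codes: 0..3 = A,C,G,T; 4 = anything else (missing/ambiguous)
_CODE = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class Alignment:
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("one sequence per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment must have at least one site")
        seqs = []
        for name, seq in zip(self.taxa, self.sequences):
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - set(AMBIGUITY)
            if bad:
                raise AlignmentError(
                    f"sequence {name!r} contains non-IUPAC characters {sorted(bad)}"
                )
            seqs.append(seq)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "sequences", tuple(seqs))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise AlignmentError(f"taxon {taxon!r} not in alignment") from None

    def codes(self) -> np.ndarray:
        """(n_taxa, n_sites) int array: 0-3 = A,C,G,T; 4 = gap/ambiguous."""
        return np.array(
            [[_CODE.get(ch, 4) for ch in seq] for seq in self.sequences],
            dtype=np.int8,
        )

    def empirical_frequencies(self) -> np.ndarray:
        """Base frequencies over unambiguous characters, order A,C,G,T."""
        codes = self.codes()
        counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
        if counts.sum() == 0:
            raise AlignmentError("alignment has no unambiguous characters")
        return counts / counts.sum()

    def site_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Compress columns into unique patterns.

        Returns ``(patterns, counts)`` where ``patterns`` is
        ``(n_patterns, n_taxa)`` of symbol strings encoded as int codes over
        the full IUPAC alphabet, and ``counts`` the column multiplicities.
        """
        cols = np.array([list(s) for s in self.sequences]).T  # (sites, taxa)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq, counts.astype(float)

    def partial_vectors(self) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
        """Leaf partial likelihood vectors on compressed patterns.

        Returns ``(leaf_partials, counts, pattern_index)`` with
        ``leaf_partials[taxon]`` of shape ``(n_patterns, 4)``.
        """
        uniq, counts = self.site_patterns()
        partials = {
            taxon: np.stack([_STATE_VECTORS[sym] for sym in uniq[:, k]])
            for k, taxon in enumerate(self.taxa)
        }
        return partials, counts, uniq
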