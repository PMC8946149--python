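"""Reference genome accessor with k-mer position indexes.

Wraps either an in-memory sequence dict or an indexed FASTA (via pyfaidx)
behind one interface used by context classification and by the synthetic
cohort generator.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class ReferenceGenome:
    """Immutable reference with fast slicing and k-mer lookup.

    Parameters
    ----------
    sequences
        Mapping of contig name to sequence string.  Stored uppercase.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("reference must contain at least one contig")
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            self._codes[name] = _CODE[arr]
        self._kmer_index: dict[int, dict[str, np.ndarray]] = {}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    # -- basic accessors ---------------------------------------------------

    @property
    def contigs(self) -> list[str]:
        return list(self._codes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._codes

    def length(self, chrom: str) -> int:
        return len(self._codes[chrom])

    def codes(self, chrom: str) -> np.ndarray:
        """Base codes (A=0,C=1,G=2,T=3, other=4) for a contig."""
        return self._codes[chrom]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Sequence for [start, end], 1-based inclusive; clipped to contig."""
        arr = self._codes[chrom]
        lo, hi = max(start - 1, 0), min(end, len(arr))
        if lo >= hi:
            return ""
        codes = arr[lo:hi]
        return "".join("ACGTN"[c] for c in codes)

    def base(self, chrom: str, pos: int) -> str:
        arr = self._codes[chrom]
        if pos < 1 or pos > len(arr):
            return ""
        return "ACGTN"[arr[pos - 1]]

    # -- k-mer indexes -----------------------------------------------------

    def _build_kmer_index(self, k: int) -> None:
        index: dict[str, list[tuple[str, np.ndarray]]] = {}
        per_kmer: dict[str, dict[str, np.ndarray]] = {}
        for chrom, arr in self._codes.items():
            if len(arr) < k:
                continue
            valid = arr < 4
            code = np.zeros(len(arr) - k + 1, dtype=np.int32)
            ok = np.ones(len(arr) - k + 1, dtype=bool)
            for off in range(k):
                seg = arr[off : off + len(code)]
                code = code * 4 + seg
                ok &= valid[off : off + len(code)]
            order = np.argsort(code, kind="stable")
            sorted_codes = code[order]
            bounds = np.searchsorted(sorted_codes, np.arange(4**k + 1))
            for kc in range(4**k):
                lo, hi = bounds[kc], bounds[kc + 1]
                if lo == hi:
                    continue
                pos = order[lo:hi]
                pos = pos[ok[pos]]
                if len(pos) == 0:
                    continue
                kmer = self._decode(kc, k)
                index.setdefault(kmer, []).append((chrom, np.sort(pos) + 1))
        for kmer, chunks in index.items():
            per_kmer[kmer] = {chrom: positions for chrom, positions in chunks}
        self._kmer_index[k] = per_kmer

    @staticmethod
    def _decode(code: int, k: int) -> str:
        out = []
        for _ in range(k):
            out.append(_BASES[code % 4])
            code //= 4
        return "".join(reversed(out))

    def kmer_positions(self, kmer: str) -> dict[str, np.ndarray]:
        """Start positions (1-based) of exact k-mer matches per contig."""
        k = len(kmer)
        if k not in self._kmer_index:
            self._build_kmer_index(k)
        return self._kmer_index[k].get(kmer.upper(), {})

    def gc_fraction(self) -> float:
        total = valid = 0
        for arr in self._codes.values():
            total += int(np.sum((arr == 1) | (arr == 2)))
            valid += int(np.sum(arr < 4))
        return total / valid if valid else 0.0


def write_fasta(ref: ReferenceGenome, path, width: int = 80) -> None:
    """Write the reference to FASTA (and build a .fai index)."""
    with open(path, "w") as fh:
        for chrom in ref.contigs:
            fh.write(f">{chrom}\n")
            seq = ref.slice(chrom, 1, ref.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    try:
        from pyfaidx import Faidx

        Faidx(str(path))
    except Exception:  # pragma: no cover - index is a convenience
        pass


def toy_chrom_names(n: int = 22) -> list[str]:
    return [f"chr{i}" for i in range(1, n + 1)]


def sequences_from_iter(pairs: Iterable[tuple[str, str]]) -> ReferenceGenome:
    return ReferenceGenome(dict(pairs))
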