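"""Low-level sequence utilities shared across the package."""

from __future__ import annotations

import gzip
import re
from typing import IO, Iterator

import numpy as np

DNA_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_NON_DNA = re.compile(r"[^ACGTN]")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, context: str = "sequence") -> None:
    """Raise ValueError if *seq* contains characters outside {A,C,G,T,N}."""
    m = _NON_DNA.search(seq)
    if m is not None:
        raise ValueError(
            f"non-DNA character {m.group()!r} at position {m.start()} in {context}"
        )


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes (vector compares)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))


def sliding_min_hamming(query: str, subject: str) -> int:
    """Minimum Hamming distance from *query* to any equal-length window of
    *subject* (sense strand only; scan the reverse complement separately).

    Returns a large sentinel (len(query)+1) when the subject is shorter than
    the query, i.e. no window exists.
    """
    q = seq_to_array(query)
    s = seq_to_array(subject)
    if len(s) < len(q):
        return len(q) + 1
    windows = np.lib.stride_tricks.sliding_window_view(s, len(q))
    return int((windows != q).sum(axis=1).min())


def open_maybe_gzip(path, mode: str = "rt") -> IO:
    """Open a path, transparently gunzipping when it ends in .gz."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def count_occurrences(needle: str, haystack: str) -> int:
    """Number of (possibly overlapping) exact occurrences of needle."""
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a FASTQ file, plain or gzipped.

    Raises ValueError naming the 0-based record index on a truncated or
    malformed record.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {idx} in {path}: {exc}"
                ) from exc
            yield rec
            idx += 1
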