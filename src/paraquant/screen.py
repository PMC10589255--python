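"""Alignment-free motif read screening and RPKM quantification.

A read is counted toward a target when it (or its reverse complement)
contains the target's core motif as an exact substring AND, anchoring the
extended motif at that core occurrence, at most ``max_mismatch`` positions
mismatch over the overlap between the read and the extended motif. Reads
are typically shorter than the extended motif, so mismatches are counted
only over the overlapping bases; the perfect-core requirement always holds.

Counts are normalised as RPKM against the total number of reads in the
FASTQ input (not genome-mapped reads) and the fixed motif length:

    RPKM = count / ((motif_length / 1e3) * (total_reads / 1e6))

A paralog's expression in a strain is flagged *reliable* only when its raw
count reaches ``min_reads`` in every replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._seq import iter_fastq, revcomp, validate_dna
from .motifs import MotifCatalog, MotifPair

logger = logging.getLogger(__name__)

DEFAULT_MOTIF_LENGTH = 130


def _anchored_mismatches(read: str, pair: MotifPair, core_pos: int,
                         budget: int) -> bool:
    """True iff anchoring the extended motif so its core sits at read
    position ``core_pos`` yields <= ``budget`` mismatches over the overlap."""
    ext = pair.extended
    core_len = len(pair.core)
    ext_start = core_pos - pair.core_offset_in_extended  # read coord of ext[0]
    lo = max(0, ext_start)
    hi = min(len(read), ext_start + len(ext))
    mism = 0
    core_end = core_pos + core_len
    for i in range(lo, hi):
        if core_pos <= i < core_end:
            continue  # core matched exactly already
        if read[i] != ext[i - ext_start]:  # 'N' never equals A/C/G/T
            mism += 1
            if mism > budget:
                return False
    return True


def _match_oriented(seq: str, pair: MotifPair, budget: int) -> bool:
    idx = seq.find(pair.core)
    while idx != -1:
        if _anchored_mismatches(seq, pair, idx, budget):
            return True
        idx = seq.find(pair.core, idx + 1)
    return False


def match_read(read_sequence: str, pair: MotifPair, max_mismatch: int = 1) -> bool:
    """Two-stage motif match of one read against one core/extended pair.

    Scans both the read and its reverse complement; multiple core
    occurrences are all tried and any passing anchoring suffices. 'N' in
    the read counts as a mismatch; characters outside {A,C,G,T,N} raise.
    """
    read = read_sequence.upper()
    validate_dna(read, "read")
    if len(read) < len(pair.core):
        return False
    if _match_oriented(read, pair, max_mismatch):
        return True
    # Occurrence of the core in revcomp(read) <=> revcomp(core) in read;
    # cheap substring test before materialising the reverse complement.
    if revcomp(pair.core) in read:
        return _match_oriented(revcomp(read), pair, max_mismatch)
    return False


@dataclass
class CountTable:
    """Raw motif-match counts for one library (one FASTQ screen)."""

    library: str
    counts: dict[str, int]
    total_reads: int
    params: dict = field(default_factory=lambda: dict(max_mismatch=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.library, t, c, self.total_reads)
             for t, c in self.counts.items()],
            columns=["library", "target", "count", "total_reads"])


def screen_library(fastq_paths, catalog: MotifCatalog,
                   max_mismatch: int = 1, library: str = "library",
                   ) -> CountTable:
    """Count reads matching each catalog motif across one or more FASTQ
    files (e.g. the two mates of a paired library, screened independently).

    Each read is counted at most once per target; a read may count toward
    both its paralog motif and the family-wide motif (independent screens).
    ``total_reads`` is the total number of FASTQ records seen.
    """
    if isinstance(fastq_paths, (str, bytes)) or hasattr(fastq_paths, "__fspath__"):
        fastq_paths = [fastq_paths]
    pairs = catalog.pairs
    # Precompute substring prefilters: a read can only match if it contains
    # the core or its reverse complement verbatim.
    prefilter = [(p, p.core, revcomp(p.core)) for p in pairs]
    counts = {p.target: 0 for p in pairs}
    family_and_paralog_warned = False
    total = 0
    for path in fastq_paths:
        for _title, seq, _qual in iter_fastq(path):
            total += 1
            read = seq.upper()
            rc_read = None
            hits = []
            for p, core, rc_core in prefilter:
                matched = False
                if core in read and _match_oriented(read, p, max_mismatch):
                    matched = True
                elif rc_core in read:
                    if rc_read is None:
                        rc_read = revcomp(read)
                    matched = _match_oriented(rc_read, p, max_mismatch)
                if matched:
                    counts[p.target] += 1
                    hits.append(p.target)
            paralog_hits = [h for h in hits if h != "ALL"]
            if len(paralog_hits) > 1 and not family_and_paralog_warned:
                logger.warning(
                    "read matched multiple paralog motifs %s; counted for "
                    "each (catalog certificates likely failed)", paralog_hits)
                warnings.warn("read matched multiple paralog motifs; "
                              "check catalog certificates", stacklevel=2)
                family_and_paralog_warned = True
    return CountTable(library=library, counts=counts, total_reads=total,
                      params=dict(max_mismatch=max_mismatch))


def screen_libraries(libraries: dict[str, list], catalog: MotifCatalog,
                     max_mismatch: int = 1) -> pd.DataFrame:
    """Screen several libraries; returns the long-format count frame with
    columns library, target, count, total_reads."""
    frames = [screen_library(paths, catalog, max_mismatch, library=name).to_frame()
              for name, paths in libraries.items()]
    return pd.concat(frames, ignore_index=True)


def rpkm_normalize(counts: pd.DataFrame,
                   motif_length: int = DEFAULT_MOTIF_LENGTH) -> pd.DataFrame:
    """Add an ``rpkm`` column: count / ((motif_length/1e3) * (total/1e6)).

    Expects columns ``count`` and ``total_reads``; empty libraries
    (total_reads == 0) raise.
    """
    if (counts["total_reads"] <= 0).any():
        bad = counts.loc[counts["total_reads"] <= 0]
        raise ValueError(
            f"cannot normalise libraries with zero total reads: "
            f"{sorted(bad.get('library', bad.index).unique().tolist())}")
    out = counts.copy()
    out["rpkm"] = out["count"] / ((motif_length / 1e3)
                                  * (out["total_reads"] / 1e6))
    out.attrs["motif_length"] = motif_length
    return out


def apply_reliability_filter(matrix: pd.DataFrame, min_reads: int = 10,
                             group_cols: tuple[str, str] = ("strain", "target"),
                             ) -> pd.DataFrame:
    """Flag (strain, target) combinations reliable iff raw count >= min_reads
    in ALL replicates.

    Expects a long frame with columns strain, target, replicate, count (and
    typically rpkm). Every (strain, target) must have the same replicate
    set; missing replicates raise. Unreliable rows are retained, flagged
    False, and are meant to be excluded from downstream statistics.
    """
    required = {*group_cols, "replicate", "count"}
    missing = required - set(matrix.columns)
    if missing:
        raise ValueError(f"matrix missing columns {sorted(missing)}")
    n_reps = matrix.groupby(list(group_cols))["replicate"].nunique()
    if n_reps.nunique() > 1:
        raise ValueError(
            "unequal replicate sets across (strain, target) combinations; "
            "a missing replicate makes the all-replicates rule undefined")
    reliable = (matrix.groupby(list(group_cols))["count"]
                .transform("min") >= min_reads)
    out = matrix.copy()
    out["reliable"] = reliable
    return out
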