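"""Diagnostic motif design for near-identical tandem paralogs.

Each paralog is assigned a two-part motif: a short *core* (default 20 nt)
that occurs exactly once in the target paralog and nowhere else in the
strain's panel (both strands, parental genes included), and an *extended*
motif (default 130 nt: core plus 55-nt flanks) used downstream as a
mismatch-tolerant context check. A family-wide "ALL" motif is drawn from
the shared first-exon segment common to every paralog and absent from the
parental genes.

Design guarantees are explicit: the extended motif of every target keeps a
minimum Hamming distance (default 2) to every window of every non-target
sequence on both strands, so an error-free read from a non-target paralog
can never pass the one-mismatch read screen. `verify_uniqueness` recomputes
these guarantees exhaustively and returns a certificate table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (count_occurrences, revcomp, seq_to_array,
                   sliding_min_hamming)
from .panel import ParalogPanel

FAMILY_TARGET = "ALL"


class UndesignableParalogError(ValueError):
    """No core window satisfying all uniqueness constraints exists."""


@dataclass(frozen=True)
class MotifPair:
    """A core/extended motif pair for one target.

    ``source_position`` is the 0-based start of the extended motif on the
    sense strand of the target sequence; the core begins
    ``core_offset_in_extended`` nt into the extended motif.
    """

    target: str
    core: str
    extended: str
    core_offset_in_extended: int
    source_position: int

    def __post_init__(self):
        off = self.core_offset_in_extended
        if self.extended[off:off + len(self.core)] != self.core:
            raise ValueError(
                f"core does not occur in extended motif at offset {off} "
                f"for target {self.target}"
            )


@dataclass
class MotifCatalog:
    """One MotifPair per paralog plus the family-wide pair."""

    strain: str
    pairs: list[MotifPair]
    design_params: dict = field(default_factory=lambda: dict(
        core_len=20, flank=55, max_mismatch=1, min_cross_distance=2))

    @property
    def targets(self) -> list[str]:
        return [p.target for p in self.pairs]

    def pair_for(self, target: str) -> MotifPair:
        for p in self.pairs:
            if p.target == target:
                return p
        raise KeyError(target)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(p.target, p.core, p.extended, p.core_offset_in_extended,
              p.source_position) for p in self.pairs],
            columns=["target", "core", "extended", "core_offset_in_extended",
                     "source_position"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, strain: str = "", **design_params) -> "MotifCatalog":
        df = pd.read_csv(path, sep="\t")
        pairs = [MotifPair(r.target, r.core, r.extended,
                           int(r.core_offset_in_extended),
                           int(r.source_position))
                 for r in df.itertuples()]
        cat = cls(strain=strain, pairs=pairs)
        cat.design_params.update(design_params)
        return cat


def find_diagnostic_sites(panel: ParalogPanel) -> dict[str, list[int]]:
    """Per-paralog positions at which its base differs from every other
    paralog's base in the (gapless) column.

    Sequences must be equal length (co-linear paralogs or a user-supplied
    gapless alignment). A column containing 'N' or a gap character in any
    paralog is treated as non-diagnostic for everyone.
    """
    seqs = [p.sequence for p in panel.paralogs]
    ids = [p.id for p in panel.paralogs]
    if len(seqs) == 0:
        return {}
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            "paralog sequences differ in length; provide a gapless alignment "
            "of equal-length sequences"
        )
    if len(seqs) == 1:
        return {ids[0]: []}
    mat = np.vstack([seq_to_array(s) for s in seqs])  # (k, L)
    ambiguous = (mat == ord("N")).any(axis=0) | (mat == ord("-")).any(axis=0)
    out: dict[str, list[int]] = {}
    k = len(seqs)
    for i in range(k):
        diff_all = np.ones(mat.shape[1], dtype=bool)
        for j in range(k):
            if j != i:
                diff_all &= mat[i] != mat[j]
        diff_all &= ~ambiguous
        out[ids[i]] = [int(x) for x in np.nonzero(diff_all)[0]]
    return out


def _nontarget_sequences(panel: ParalogPanel, target: str) -> list[str]:
    seqs = [p.sequence for p in panel.paralogs if p.id != target]
    seqs.extend(panel.parental_sequences.values())
    return seqs


def _min_cross_hamming(extended: str, others: list[str]) -> int:
    """Min Hamming distance of extended motif to any window of any other
    sequence, both strands."""
    best = len(extended) + 1
    rc = revcomp(extended)
    for s in others:
        best = min(best, sliding_min_hamming(extended, s),
                   sliding_min_hamming(rc, s))
        if best == 0:
            return 0
    return best


def _core_is_unique(core: str, target_seq: str | None, others: list[str]) -> bool:
    """Core occurs exactly once in target (both strands) and never in any
    other sequence on either strand. target_seq None skips the target check
    (used for presence-in-all family motifs)."""
    rc = revcomp(core)
    if target_seq is not None:
        n = count_occurrences(core, target_seq) + count_occurrences(rc, target_seq)
        if n != 1:
            return False
    for s in others:
        if core in s or rc in s:
            return False
    return True


def _window_clean(window: str) -> bool:
    return "N" not in window


def design_motifs(panel: ParalogPanel, core_len: int = 20, flank: int = 55,
                  max_mismatch: int = 1, min_cross_distance: int = 2,
                  exclusion_zones: dict[str, list[tuple[int, int]]] | None = None,
                  ) -> MotifCatalog:
    """Design one diagnostic MotifPair per paralog plus the family pair.

    Candidate cores are windows centred on a diagnostic site; among
    candidates whose core is strain-unique and whose extended motif keeps
    >= min_cross_distance mismatches to all non-target windows, the one
    maximising that distance is chosen (leftmost on ties).

    ``exclusion_zones`` optionally maps paralog id to half-open [start, end)
    intervals the extended motif must not overlap (e.g. to keep motifs away
    from transcript ends).

    Raises
    ------
    UndesignableParalogError
        If some paralog admits no qualifying core window.
    """
    ext_len = core_len + 2 * flank
    sites = find_diagnostic_sites(panel)
    exclusion_zones = exclusion_zones or {}
    pairs: list[MotifPair] = []

    single_copy = len(panel.paralogs) == 1
    for paralog in panel.paralogs:
        seq = paralog.sequence
        others = _nontarget_sequences(panel, paralog.id)
        best: tuple[int, int] | None = None  # (-distance, ext_start)
        if single_copy:
            # any window is family-unique; take the leftmost one that
            # clears the parental-sequence checks
            for ext_start in range(len(seq) - ext_len + 1):
                extended = seq[ext_start:ext_start + ext_len]
                if not _window_clean(extended):
                    continue
                if any(ext_start < z_end and ext_start + ext_len > z_start
                       for z_start, z_end
                       in exclusion_zones.get(paralog.id, [])):
                    continue
                core = extended[flank:flank + core_len]
                if not _core_is_unique(core, seq, others):
                    continue
                if others and _min_cross_hamming(extended, others) \
                        < min_cross_distance:
                    continue
                best = (0, ext_start)
                break
        for site in ([] if single_copy else sites.get(paralog.id, [])):
            core_start = site - core_len // 2
            ext_start = core_start - flank
            if ext_start < 0 or ext_start + ext_len > len(seq):
                continue
            if any(ext_start < z_end and ext_start + ext_len > z_start
                   for z_start, z_end in exclusion_zones.get(paralog.id, [])):
                continue
            extended = seq[ext_start:ext_start + ext_len]
            if not _window_clean(extended):
                continue
            core = seq[core_start:core_start + core_len]
            if not _core_is_unique(core, seq, others):
                continue
            dist = _min_cross_hamming(extended, others)
            if dist < min_cross_distance:
                continue
            key = (-dist, ext_start)
            if best is None or key < best:
                best = key
        if best is None:
            raise UndesignableParalogError(
                f"undesignable paralog {paralog.id!r} in strain "
                f"{panel.strain!r}: no core window with a unique "
                f"{core_len}-mer and cross-distance >= {min_cross_distance}"
            )
        ext_start = best[1]
        extended = seq[ext_start:ext_start + ext_len]
        pairs.append(MotifPair(
            target=paralog.id, core=extended[flank:flank + core_len],
            extended=extended, core_offset_in_extended=flank,
            source_position=ext_start))

    # Family-wide motif from the shared segment, screened against parentals.
    shared = panel.family_shared_segment
    if shared:
        if len(shared) < ext_len:
            raise ValueError(
                f"family_shared_segment shorter than extended motif "
                f"({len(shared)} < {ext_len})"
            )
        parentals = list(panel.parental_sequences.values())
        best = None
        for ext_start in range(len(shared) - ext_len + 1):
            extended = shared[ext_start:ext_start + ext_len]
            if not _window_clean(extended):
                continue
            core = extended[flank:flank + core_len]
            if not _core_is_unique(core, None, parentals):
                continue
            if not all(core in p.sequence or revcomp(core) in p.sequence
                       for p in panel.paralogs):
                continue
            dist = _min_cross_hamming(extended, parentals)
            if dist < min_cross_distance:
                continue
            key = (-dist, ext_start)
            if best is None or key < best:
                best = key
        if best is None:
            raise UndesignableParalogError(
                f"undesignable family motif for strain {panel.strain!r}"
            )
        ext_start = best[1]
        extended = shared[ext_start:ext_start + ext_len]
        pairs.append(MotifPair(
            target=FAMILY_TARGET, core=extended[flank:flank + core_len],
            extended=extended, core_offset_in_extended=flank,
            source_position=ext_start))

    return MotifCatalog(strain=panel.strain, pairs=pairs,
                        design_params=dict(core_len=core_len, flank=flank,
                                           max_mismatch=max_mismatch,
                                           min_cross_distance=min_cross_distance))


def verify_uniqueness(catalog: MotifCatalog, panel: ParalogPanel) -> pd.DataFrame:
    """Exhaustively recompute the uniqueness guarantees of a catalog.

    For each pair, reports (a) exact core occurrence counts per panel and
    parental sequence on both strands and (b) the minimum Hamming distance
    of the extended motif to every equal-length window of every non-target
    sequence on both strands. A paralog pair passes iff its core count is 1
    in the target, 0 elsewhere, and (b) >= min_cross_distance; the family
    pair passes iff its core occurs in every paralog, never in a parental,
    and its parental cross-distance >= min_cross_distance.

    Returns a DataFrame with one row per pair; failures are reported, never
    raised.
    """
    mcd = catalog.design_params.get("min_cross_distance", 2)
    rows = []
    for pair in catalog.pairs:
        rc = revcomp(pair.core)
        core_counts = {}
        for p in panel.paralogs:
            core_counts[p.id] = (count_occurrences(pair.core, p.sequence)
                                 + count_occurrences(rc, p.sequence))
        for name, seq in panel.parental_sequences.items():
            core_counts[f"parental:{name}"] = (
                count_occurrences(pair.core, seq)
                + count_occurrences(rc, seq))
        if pair.target == FAMILY_TARGET:
            nontargets = list(panel.parental_sequences.values())
            counts_ok = (all(core_counts[p.id] >= 1 for p in panel.paralogs)
                         and all(core_counts[f"parental:{n}"] == 0
                                 for n in panel.parental_sequences))
        else:
            nontargets = _nontarget_sequences(panel, pair.target)
            counts_ok = all(
                (c == 1 if name == pair.target else c == 0)
                for name, c in core_counts.items())
        dist = _min_cross_hamming(pair.extended, nontargets) if nontargets \
            else len(pair.extended) + 1
        rows.append(dict(target=pair.target,
                         core_counts=json.dumps(core_counts),
                         min_cross_hamming=dist,
                         counts_ok=counts_ok,
                         distance_ok=dist >= mcd,
                         passed=counts_ok and dist >= mcd))
    return pd.DataFrame(rows)
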