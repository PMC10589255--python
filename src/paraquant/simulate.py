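"""Synthetic data with known ground truth.

Emulates the statistical structure the pipeline assumes: a strain panel of
3–6 near-identical (~99%) tandem paralogs of a ~5,000-nt transcript
sharing a family-specific first-exon segment; strand-specific 100-nt
paired-end libraries with three replicates per strain and per-base
substitution errors; and cell-type-labelled single-cell inputs with
stage-dependent expression.

Paralogs are copies of one random template carrying per-paralog
substitutions at disjoint positions, so every substituted position is a
diagnostic site by construction (the carrier differs there from every
other paralog). The shared first exon is kept substitution-free and is
absent from the independent random decoy sequence that stands in for the
parental genes.

All outputs are byte-identical under a fixed scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp
from .panel import Paralog, ParalogPanel

DECOY_NAME = "decoy"

TEMPLATE_LENGTH = 5000
EXON_LENGTH = 300       # family-shared first-exon analog
DECOY_LENGTH = 3000
EDGE_MARGIN = 70        # keep substitutions clear of ends (flank 55 + core)


class IndistinguishableParalogsError(ValueError):
    """Multiple paralogs requested with zero diagnostic substitutions."""


@dataclass
class StrainSpec:
    """One simulated strain.

    ``paralog_proportions`` give each paralog's share of the whole library
    (they sum to the family's share); ``background_fraction`` is the share
    drawn from the decoy sequence, so proportions + background must sum
    to 1.
    """

    name: str
    copy_number: int
    paralog_proportions: list[float]
    divergence_sites: int = 5
    background_fraction: float = 0.0

    def __post_init__(self):
        if self.copy_number != len(self.paralog_proportions):
            raise ValueError(
                f"strain {self.name}: copy_number={self.copy_number} but "
                f"{len(self.paralog_proportions)} proportions given")
        if any(p < 0 for p in self.paralog_proportions):
            raise ValueError(f"strain {self.name}: negative proportion")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction outside [0, 1]")
        total = sum(self.paralog_proportions) + self.background_fraction
        if abs(total - 1.0) > 1e-8:
            raise ValueError(
                f"strain {self.name}: proportions + background sum to "
                f"{total:.6f}, expected 1")
        if self.copy_number > 1 and self.divergence_sites == 0:
            raise IndistinguishableParalogsError(
                f"strain {self.name}: {self.copy_number} paralogs with "
                f"divergence_sites=0 cannot be told apart")

    @property
    def paralog_ids(self) -> list[str]:
        return [f"{self.name}_p{i + 1}" for i in range(self.copy_number)]


@dataclass
class SimScenario:
    """Study design for the simulator.

    Defaults mirror the bulk study conditions: four isogenic strains
    spanning the common 3–6 copy-number range, three biological replicates
    each, strand-specific 100-nt paired-end reads.
    """

    seed: int
    strains: list[StrainSpec]
    read_length: int = 100
    error_rate: float = 0.0
    paired: bool = True
    library_size: int = 100_000   # fragments per replicate
    n_replicates: int = 3
    strand_protocol: str = "dutp"  # mate 1 antisense, mate 2 sense; or "fr"
    max_insert: int = 300

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.strand_protocol not in ("dutp", "fr"):
            raise ValueError("strand_protocol must be 'dutp' or 'fr'")
        names = [s.name for s in self.strains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strain names")


@dataclass
class SimTruth:
    """Ground truth recorded during simulation."""

    bulk: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: strain, replicate, source, fragments, library_size
    substitutions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    cell_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    cell_counts: pd.DataFrame = field(default_factory=pd.DataFrame)


def default_scenario(seed: int, library_size: int = 100_000,
                     error_rate: float = 0.001,
                     family_share_per_copy: float = 0.01) -> SimScenario:
    """The canonical four-strain design: copy numbers 3, 4, 5, 6, each copy
    contributing an equal per-copy share of the library, remainder decoy
    background."""
    strains = []
    for name, cn in zip(("S3", "S4", "S5", "S6"), (3, 4, 5, 6)):
        share = family_share_per_copy
        strains.append(StrainSpec(
            name=name, copy_number=cn,
            paralog_proportions=[share] * cn,
            divergence_sites=5,
            background_fraction=round(1 - share * cn, 12)))
    return SimScenario(seed=seed, strains=strains, error_rate=error_rate,
                       library_size=library_size)


# ---------------------------------------------------------------------------
# Panels

def simulate_panel(scenario: SimScenario,
                   template_length: int = TEMPLATE_LENGTH,
                   exon_length: int = EXON_LENGTH,
                   decoy_length: int = DECOY_LENGTH,
                   ) -> tuple[dict[str, ParalogPanel], SimTruth]:
    """Generate one ParalogPanel per strain plus the substitution truth.

    Each strain's paralogs are copies of a shared random template with
    ``divergence_sites`` substitutions at positions disjoint across
    paralogs (and clear of the shared first exon and sequence ends), so
    every substituted position is a diagnostic site for its carrier. Each
    paralog's substitutions are placed within one ~110-nt cluster inside a
    paralog-private block of the template, guaranteeing that some 130-nt
    window holds at least two of its diagnostic sites — the condition for
    designing extended motifs with the default cross-distance of 2. The
    decoy/parental sequence is independent random DNA.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    template = random_dna(rng, template_length)
    decoy = random_dna(rng, decoy_length)
    shared_exon = template[:exon_length]

    panels: dict[str, ParalogPanel] = {}
    truth = SimTruth()
    lo = exon_length + EDGE_MARGIN
    hi = template_length - EDGE_MARGIN
    cluster_span = 110
    for s_idx, spec in enumerate(scenario.strains):
        srng = np.random.default_rng([scenario.seed, 1, s_idx])
        k, d = spec.copy_number, spec.divergence_sites
        block = (hi - lo) // max(k, 1)
        if d > cluster_span or block < cluster_span + 10:
            raise ValueError("too many divergence sites for template length")
        paralogs = []
        subs: dict[str, list[int]] = {}
        for i, pid in enumerate(spec.paralog_ids):
            seq = list(template)
            if d > 0:
                block_lo = lo + i * block
                start = int(srng.integers(block_lo,
                                          block_lo + block - cluster_span))
                offsets = srng.choice(cluster_span, size=d, replace=False)
                mine = sorted(int(start + o) for o in offsets)
            else:
                mine = []
            for pos in mine:
                current = seq[pos]
                alternatives = [b for b in "ACGT" if b != current]
                seq[pos] = alternatives[srng.integers(0, 3)]
            paralogs.append(Paralog(pid, "".join(seq), i + 1))
            subs[pid] = mine
        panels[spec.name] = ParalogPanel(
            strain=spec.name, paralogs=paralogs,
            family_shared_segment=shared_exon,
            parental_sequences={DECOY_NAME: decoy})
        truth.substitutions[spec.name] = subs
    return panels, truth


# ---------------------------------------------------------------------------
# Bulk reads

def _apply_errors(read: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0:
        return read
    n_err = rng.binomial(len(read), error_rate)
    if n_err == 0:
        return read
    pos = rng.choice(len(read), size=n_err, replace=False)
    chars = list(read)
    for p in pos:
        current = chars[p]
        alternatives = [b for b in "ACGT" if b != current]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_bulk_reads(panel: ParalogPanel, strain_spec: StrainSpec,
                        scenario: SimScenario, replicate: int,
                        out_dir) -> dict[str, int]:
    """Write one replicate library as FASTQ and return fragment truth.

    Fragments are drawn multinomially across paralogs (and the decoy
    background) per the strain's proportions, with uniform start positions
    and insert lengths, per-base substitution errors at
    ``scenario.error_rate``, and the configured strand protocol (default
    dUTP: mate 1 antisense, mate 2 sense). Reads are written grouped by
    source sequence; read order carries no information for the screen.

    Returns {source_name: fragment count} with the library size recovered
    exactly as the sum. Files are ``<strain>_rep<r>_R1.fastq`` (and
    ``_R2``) under ``out_dir``; a zero library size yields valid empty
    FASTQ files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s_idx = next(i for i, s in enumerate(scenario.strains)
                 if s.name == strain_spec.name)
    rng = np.random.default_rng([scenario.seed, 2, s_idx, replicate])

    sources = [(pid, panel.sequence_of(pid))
               for pid in strain_spec.paralog_ids]
    probs = list(strain_spec.paralog_proportions)
    if strain_spec.background_fraction > 0:
        if DECOY_NAME not in panel.parental_sequences:
            raise ValueError("background requested but panel has no decoy")
        sources.append((DECOY_NAME, panel.parental_sequences[DECOY_NAME]))
        probs.append(strain_spec.background_fraction)
    counts = rng.multinomial(scenario.library_size, np.asarray(probs))

    L = scenario.read_length
    qual = "I" * L
    prefix = f"{strain_spec.name}_rep{replicate}"
    r1_path = out_dir / f"{prefix}_R1.fastq"
    r2_path = out_dir / f"{prefix}_R2.fastq"
    r2_fh = open(r2_path, "w") if scenario.paired else None
    truth: dict[str, int] = {}
    with open(r1_path, "w") as r1_fh:
        for (name, seq), n in zip(sources, counts):
            truth[name] = int(n)
            max_ins = min(scenario.max_insert, len(seq))
            for i in range(int(n)):
                ins = int(rng.integers(L, max_ins + 1))
                start = int(rng.integers(0, len(seq) - ins + 1))
                frag = seq[start:start + ins]
                sense = frag[:L]
                antisense = revcomp(frag)[:L]
                if scenario.strand_protocol == "dutp":
                    m1, m2 = antisense, sense
                else:
                    m1, m2 = sense, antisense
                m1 = _apply_errors(m1, rng, scenario.error_rate)
                rid = f"{prefix}:{name}:{i}"
                r1_fh.write(f"@{rid}/1\n{m1}\n+\n{qual}\n")
                if r2_fh is not None:
                    m2 = _apply_errors(m2, rng, scenario.error_rate)
                    r2_fh.write(f"@{rid}/2\n{m2}\n+\n{qual}\n")
    if r2_fh is not None:
        r2_fh.close()
    return truth


def simulate_bulk_study(scenario: SimScenario, out_dir,
                        ) -> tuple[dict[str, ParalogPanel], SimTruth]:
    """Panels plus every strain x replicate library under ``out_dir``."""
    panels, truth = simulate_panel(scenario)
    rows = []
    for spec in scenario.strains:
        for rep in range(scenario.n_replicates):
            frag_truth = simulate_bulk_reads(panels[spec.name], spec,
                                             scenario, rep, out_dir)
            for source, n in frag_truth.items():
                rows.append(dict(strain=spec.name, replicate=rep,
                                 source=source, fragments=n,
                                 library_size=scenario.library_size))
    truth.bulk = pd.DataFrame(rows)
    return panels, truth


# ---------------------------------------------------------------------------
# Single cells

@dataclass
class CellTypeProfile:
    """Mean reads per cell for each gene in one cell type."""

    name: str
    proportion: float
    expression: dict[str, float]  # gene -> mean cDNA reads per cell


def _barcode(index: int, length: int = 16) -> str:
    bases = "ACGT"
    out = []
    for _ in range(length):
        out.append(bases[index % 4])
        index //= 4
    return "".join(out)


def simulate_cells(panel: ParalogPanel, cell_type_profiles: list[CellTypeProfile],
                   n_cells: int, scenario: SimScenario, out_dir,
                   barcode_len: int = 16, umi_len: int = 12,
                   ) -> tuple[dict[str, Path], SimTruth]:
    """Barcoded paired FASTQ + annotation TSV + cells x genes matrix.

    R1 carries barcode+UMI, R2 a sense-strand cDNA read. Per-cell gene
    counts are Poisson around the cell type's profile means; the written
    matrix equals the realised read counts exactly. Genes are the panel's
    paralogs plus any profile key matching a parental/decoy name.

    Raises on duplicate cell-type names (which would assign one barcode
    set to two types).
    """
    names = [p.name for p in cell_type_profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell type names in profiles")
    props = np.array([p.proportion for p in cell_type_profiles], dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("cell type proportions must sum to 1")
    genes = sorted({g for p in cell_type_profiles for g in p.expression})
    seqs = {}
    for g in genes:
        if g in panel.ids:
            seqs[g] = panel.sequence_of(g)
        elif g in panel.parental_sequences:
            seqs[g] = panel.parental_sequences[g]
        else:
            raise KeyError(f"profile gene {g!r} not in panel")

    rng = np.random.default_rng([scenario.seed, 3])
    type_of_cell = rng.choice(len(names), size=n_cells, p=props)
    barcodes = [_barcode(i, barcode_len) for i in range(n_cells)]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1_path = out_dir / "cells_R1.fastq"
    r2_path = out_dir / "cells_R2.fastq"
    annot_path = out_dir / "cell_annotation.tsv"
    L = scenario.read_length
    qual2 = "I" * L
    counts = np.zeros((n_cells, len(genes)), dtype=int)
    with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
        for ci in range(n_cells):
            profile = cell_type_profiles[type_of_cell[ci]]
            for gi, g in enumerate(genes):
                mean = profile.expression.get(g, 0.0)
                n_reads = rng.poisson(mean) if mean > 0 else 0
                counts[ci, gi] = n_reads
                seq = seqs[g]
                for ri in range(n_reads):
                    start = int(rng.integers(0, len(seq) - L + 1))
                    cdna = _apply_errors(seq[start:start + L], rng,
                                         scenario.error_rate)
                    umi = random_dna(rng, umi_len)
                    rid = f"cell{ci}:{g}:{ri}"
                    r1_bases = barcodes[ci] + umi
                    r1.write(f"@{rid}/1\n{r1_bases}\n+\n{'I' * len(r1_bases)}\n")
                    r2.write(f"@{rid}/2\n{cdna}\n+\n{qual2}\n")
    with open(annot_path, "w") as fh:
        for ci in range(n_cells):
            fh.write(f"{barcodes[ci]}\t{names[type_of_cell[ci]]}\n")

    matrix = pd.DataFrame(counts, index=barcodes, columns=genes)
    from .cells import write_matrix
    write_matrix(matrix, out_dir / "matrix")

    truth = SimTruth()
    truth.cell_means = pd.DataFrame(
        [{**{"cell_type": p.name}, **{g: p.expression.get(g, 0.0)
                                      for g in genes}}
         for p in cell_type_profiles]).set_index("cell_type")
    truth.cell_counts = matrix.groupby(
        pd.Series([names[t] for t in type_of_cell], index=barcodes)).sum()
    paths = dict(r1=r1_path, r2=r2_path, annotation=annot_path,
                 matrix=out_dir / "matrix")
    return paths, truth
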