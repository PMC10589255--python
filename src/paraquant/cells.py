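"""Cell-type-resolved paralog expression.

Two complementary routes:

* matrix route — take an externally normalised cells x genes matrix plus a
  barcode -> cell-type annotation, apply the QC filters (genes detected in
  >= 3 cells; cells with 200–8000 detected genes), and run per-cell-type
  Wilcoxon rank-sum marker tests, percent-expressing summaries and the
  family-aggregate pseudo-gene.
* read route — screen raw 10x-style paired FASTQ with the diagnostic motif
  catalog, assigning each cDNA read (R2) to a cell type via the barcode at
  the start of R1, and report per-(cell type, target) counts and RPKM.

Clustering, doublet removal and cluster annotation are consumed as inputs
(the annotation table), never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.io import mmread, mmwrite
from statsmodels.stats.multitest import multipletests

from ._seq import iter_fastq
from .motifs import MotifCatalog
from .screen import DEFAULT_MOTIF_LENGTH, match_read


@dataclass(frozen=True)
class Chemistry:
    """Barcode layout of read 1 (10x-style): barcode then UMI."""

    barcode_len: int = 16
    umi_len: int = 12  # 10 for 10x v2, 12 for v3

    @classmethod
    def named(cls, name: str) -> "Chemistry":
        presets = {"10x-v2": cls(16, 10), "10x-v3": cls(16, 12)}
        if name not in presets:
            raise ValueError(f"unknown chemistry {name!r}; "
                             f"choose from {sorted(presets)}")
        return presets[name]


def load_annotation(path) -> pd.Series:
    """Read a barcode -> cell_type TSV (two columns, header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0].lower() in ("barcode", "cell"):
        df = df.iloc[1:]
    ann = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                    name="cell_type")
    if ann.index.duplicated().any():
        raise ValueError("duplicate barcodes in annotation")
    return ann


def filter_cells_genes(matrix: pd.DataFrame, min_cells: int = 3,
                       min_genes: int = 200, max_genes: int = 8000,
                       ) -> pd.DataFrame:
    """QC filter a cells x genes count matrix.

    Genes detected (count > 0) in >= ``min_cells`` cells are kept; then
    cells with a detected-gene count in [min_genes, max_genes] (inclusive
    bounds) are kept. The gene filter runs first and the pass is not
    iterated. Raises if nothing survives.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative counts in matrix")
    detected_per_gene = (matrix > 0).sum(axis=0)
    genes_kept = detected_per_gene[detected_per_gene >= min_cells].index
    out = matrix[genes_kept]
    genes_per_cell = (out > 0).sum(axis=1)
    cells_kept = genes_per_cell[(genes_per_cell >= min_genes)
                                & (genes_per_cell <= max_genes)].index
    out = out.loc[cells_kept]
    if out.shape[0] == 0 or out.shape[1] == 0:
        raise ValueError("matrix empty after QC filtering")
    return out


def normalize_cp10k_log1p(matrix: pd.DataFrame) -> pd.DataFrame:
    """Default stand-in normalisation: log1p of counts per 10,000.

    A deliberately simple library-size normalisation for feeding the
    marker tests when no externally normalised matrix (e.g. a
    variance-stabilised one) is supplied.
    """
    lib = matrix.sum(axis=1).replace(0, np.nan)
    return np.log1p(matrix.div(lib, axis=0) * 1e4).fillna(0.0)


@dataclass
class CellScreenResult:
    """Per-(cell type, target) motif counts from raw 10x-style reads."""

    counts: pd.DataFrame        # cell_type x target count matrix
    reads_per_type: pd.Series   # reads assigned to each annotated type
    discarded_reads: int        # reads whose barcode had no annotation
    total_reads: int

    def rpkm(self, motif_length: int = DEFAULT_MOTIF_LENGTH,
             denominator: str = "per-type") -> pd.DataFrame:
        """RPKM per (cell type, target).

        ``denominator='per-type'`` divides by the reads assigned to that
        cell type (types with few cells stay comparable);
        ``'whole-library'`` divides by all reads in the input.
        """
        if denominator == "per-type":
            denom = self.reads_per_type.astype(float)
        elif denominator == "whole-library":
            denom = pd.Series(float(self.total_reads),
                              index=self.counts.index)
        else:
            raise ValueError("denominator must be 'per-type' or "
                             "'whole-library'")
        if (denom <= 0).any():
            raise ValueError("cell type with zero assigned reads")
        return self.counts.div((motif_length / 1e3) * (denom / 1e6), axis=0)


def screen_cells(r1_path, r2_path, catalog: MotifCatalog,
                 annotation: pd.Series, chemistry: Chemistry = Chemistry(),
                 max_mismatch: int = 1) -> CellScreenResult:
    """Screen barcoded paired reads: barcode from R1, motif match on R2.

    Reads whose barcode is not in the annotation are discarded and
    tallied. The invariant sum(reads_per_type) + discarded == total_reads
    holds exactly.
    """
    if annotation.index.duplicated().any():
        raise ValueError("duplicate barcodes in annotation")
    ann = annotation.to_dict()
    types = sorted(set(ann.values()))
    targets = catalog.targets
    counts = {(t, g): 0 for t in types for g in targets}
    reads_per_type = dict.fromkeys(types, 0)
    discarded = 0
    total = 0
    bc_len = chemistry.barcode_len
    for (t1, s1, _q1), (_t2, s2, _q2) in zip(iter_fastq(r1_path),
                                             iter_fastq(r2_path),
                                             strict=True):
        total += 1
        if len(s1) < bc_len:
            raise ValueError(
                f"R1 read {t1!r} shorter than barcode length {bc_len}")
        cell_type = ann.get(s1[:bc_len].upper())
        if cell_type is None:
            discarded += 1
            continue
        reads_per_type[cell_type] += 1
        for pair in catalog.pairs:
            if match_read(s2, pair, max_mismatch):
                counts[(cell_type, pair.target)] += 1
    mat = pd.DataFrame(
        [[counts[(t, g)] for g in targets] for t in types],
        index=pd.Index(types, name="cell_type"),
        columns=pd.Index(targets, name="target"))
    return CellScreenResult(counts=mat,
                            reads_per_type=pd.Series(reads_per_type),
                            discarded_reads=discarded, total_reads=total)


def marker_test(matrix: pd.DataFrame, labels: pd.Series,
                alpha: float = 0.05) -> pd.DataFrame:
    """Per-(gene, cell type) Wilcoxon rank-sum marker tests.

    For each gene and type: two-sided rank-sum of cells in the type versus
    all other cells; Benjamini–Hochberg adjustment across every (gene,
    type) test. A type is flagged ``higher`` when adjusted p < alpha AND
    its mean exceeds the rest-mean; per gene, ``peak`` marks the flagged
    type with the highest mean. Types with < 2 cells get NaN statistics.

    Returns a tidy frame: gene, cell_type, mean, rest_mean,
    pct_expressing, p, p_adj, higher, peak.
    """
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("cells without a label in the annotation")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("marker test requires >= 2 cell types")
    rows = []
    for gene in matrix.columns:
        x = matrix[gene].to_numpy(dtype=float)
        for t in types:
            mask = (labels == t).to_numpy()
            in_t, rest = x[mask], x[~mask]
            mean_t = float(in_t.mean()) if in_t.size else np.nan
            pct = float(100.0 * (in_t > 0).mean()) if in_t.size else np.nan
            if in_t.size < 2 or rest.size < 2:
                p = np.nan
            elif np.ptp(x) == 0:
                p = 1.0  # identical expression everywhere: no evidence
            else:
                p = float(sps.mannwhitneyu(in_t, rest,
                                           alternative="two-sided").pvalue)
            rows.append(dict(gene=gene, cell_type=t, mean=mean_t,
                             rest_mean=float(rest.mean()) if rest.size else np.nan,
                             pct_expressing=pct, p=p))
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(out.loc[tested, "p"],
                                                 method="fdr_bh")[1]
    out["higher"] = (out["p_adj"] < alpha) & (out["mean"] > out["rest_mean"])
    out["peak"] = False
    for gene, g in out.groupby("gene"):
        sig = g.loc[g["higher"]]
        if len(sig):
            out.loc[sig["mean"].idxmax(), "peak"] = True
    return out


def aggregate_family(matrix: pd.DataFrame, family: list[str],
                     name: str = "family_aggregate") -> pd.DataFrame:
    """Append a pseudo-gene column summing the family members' counts per
    cell; the aggregate then flows through the same summaries as any gene."""
    if not family:
        raise ValueError("empty family gene list")
    missing = [g for g in family if g not in matrix.columns]
    if missing:
        raise KeyError(f"family genes absent from matrix: {missing}")
    out = matrix.copy()
    out[name] = matrix[family].sum(axis=1)
    return out


def cell_type_table(matrix: pd.DataFrame, labels: pd.Series,
                    family: list[str] | None = None,
                    normalized: pd.DataFrame | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Full per-(cell type, gene) summary table.

    Counts (with the family aggregate appended when ``family`` is given)
    drive percent-expressing; marker tests run on ``normalized`` when
    supplied, else on log1p counts-per-10k of the (aggregated) counts.
    """
    counts = aggregate_family(matrix, family) if family else matrix
    norm = normalized if normalized is not None else normalize_cp10k_log1p(counts)
    if family and "family_aggregate" not in norm.columns:
        norm = aggregate_family(norm, family) if normalized is not None else norm
    table = marker_test(norm, labels, alpha=alpha)
    # percent-expressing recomputed from raw counts (detection, not level)
    pct = {}
    lab = labels.reindex(counts.index)
    for gene in counts.columns:
        for t, g in counts.groupby(lab):
            pct[(gene, t)] = float(100.0 * (g[gene] > 0).mean())
    table["pct_expressing"] = [
        pct.get((r.gene, r.cell_type), np.nan) for r in table.itertuples()]
    return table


# ---------------------------------------------------------------------------
# Matrix I/O (MTX + label TSVs, 10x convention: features x cells on disk)

def write_matrix(matrix: pd.DataFrame, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"),
            sparse.csr_matrix(matrix.to_numpy().T))
    (out / "barcodes.tsv").write_text("\n".join(matrix.index) + "\n")
    (out / "features.tsv").write_text("\n".join(matrix.columns) + "\n")


def read_matrix(in_dir) -> pd.DataFrame:
    d = Path(in_dir)
    mat = mmread(str(d / "matrix.mtx")).toarray().T
    barcodes = (d / "barcodes.tsv").read_text().split()
    features = (d / "features.tsv").read_text().split()
    return pd.DataFrame(mat, index=barcodes, columns=features)
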