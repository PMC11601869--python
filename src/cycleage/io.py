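"""Readers and writers for the pipeline's plain-text formats.

Sample columns follow the ``<genotype>_<age>m_r<rep>`` convention for
expression and proteome CSVs; single-cell data use MatrixMarket MTX with
features.tsv/barcodes.tsv; gene sets use GMT; cohort tables are TSV.
Writers and readers round-trip for decimal representations.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .cyclic_detect import CyclicCallSet, ClusterResult, ProteomeTable, TimecourseMatrix
from .exceptions import ParseError
from .signature import GeneSet

__all__ = [
    "write_expression_csv", "read_expression_csv",
    "write_proteome_csv", "read_proteome_csv",
    "write_mtx_dir", "read_mtx_dir",
    "write_gmt", "read_gmt",
    "write_cohort_tsv", "read_cohort_tsv",
    "write_calls_tsv", "write_partition_json", "write_newick",
    "read_ortholog_map", "map_gene_set",
]

_SAMPLE_RE = re.compile(r"^(?P<genotype>.+)_(?P<age>\d+)m_r(?P<rep>\d+)$")
_FLOAT_FMT = "%.10g"


def _parse_sample(name: str, where: str) -> tuple[str, int, int]:
    m = _SAMPLE_RE.match(name)
    if not m:
        raise ParseError(f"{where}: malformed sample column {name!r} "
                         "(expected <genotype>_<age>m_r<rep>)")
    return m["genotype"], int(m["age"]), int(m["rep"])


def write_expression_csv(tc: TimecourseMatrix, path) -> None:
    df = tc.values.copy()
    df.columns = [f"{tc.genotype}_{tp}m_r{rep}" for tp, rep in df.columns]
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_expression_csv(path) -> TimecourseMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    parsed = [_parse_sample(c, str(path)) for c in df.columns]
    genotypes = {g for g, _, _ in parsed}
    if len(genotypes) != 1:
        raise ParseError(f"{path}: expected a single genotype, found {sorted(genotypes)}")
    bad = df.columns[~df.apply(pd.to_numeric, errors="coerce").notna().all()]
    if len(bad):
        raise ParseError(f"{path}: non-numeric values in column {bad[0]!r}")
    df.columns = pd.MultiIndex.from_tuples(
        [(age, rep) for _, age, rep in parsed], names=["timepoint", "replicate"]
    )
    return TimecourseMatrix(values=df.astype(float), genotype=next(iter(genotypes)))


def write_proteome_csv(pt: ProteomeTable, path) -> None:
    df = pt.values.copy()
    df.columns = [f"{gt}_{tp}m_r{rep}" for gt, tp, rep in df.columns]
    df.to_csv(path, float_format=_FLOAT_FMT)  # NaN -> empty cell


def read_proteome_csv(path, floor: float = 0.0, min_detect: int | None = None) -> ProteomeTable:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate protein id {dup!r}")
    parsed = [_parse_sample(c, str(path)) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(parsed, names=["genotype", "timepoint", "replicate"])
    return ProteomeTable(values=df.astype(float), floor=floor, min_detect=min_detect)


def write_mtx_dir(adata: ad.AnnData, outdir) -> None:
    """CellRanger-style triplet: genes x cells MTX + features + barcodes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    x = sparse.csr_matrix(x) if not sparse.issparse(x) else x.tocsr()
    scio.mmwrite(str(outdir / "matrix.mtx"), x.T.astype(int))
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "obs.tsv", sep="\t")


def read_mtx_dir(indir) -> ad.AnnData:
    indir = Path(indir)
    try:
        x = scio.mmread(str(indir / "matrix.mtx"))
    except Exception as exc:
        raise ParseError(f"{indir}/matrix.mtx: {exc}") from exc
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    mat = sparse.csr_matrix(x).T  # cells x genes
    if mat.shape != (len(barcodes), len(genes)):
        raise ParseError(f"{indir}: matrix shape {mat.shape} does not match "
                         f"{len(barcodes)} barcodes x {len(genes)} features")
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    obs_path = indir / "obs.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t", index_col=0)
        adata.obs = obs.loc[adata.obs_names]
    return adata


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (name, description, genes...); duplicate genes in a
    line are dropped with a warning, blank gene fields are skipped."""
    import warnings

    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g.strip()]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                warnings.warn(f"{path}:{ln}: duplicate genes in set {name!r} deduplicated")
            sets.append(GeneSet(name=name, genes=tuple(uniq), description=desc))
    if not sets:
        import warnings as _w

        _w.warn(f"{path}: empty GMT file")
    return sets


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"age_years", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_calls_tsv(calls: CyclicCallSet, path) -> None:
    calls.calls.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_partition_json(result: ClusterResult, path) -> None:
    payload = {"partition": [sorted(result.partition[0]), sorted(result.partition[1])]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_newick(result: ClusterResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(result.newick + "\n")


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV ``mouse_symbol<TAB>human_symbol``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog map needs two tab-separated columns")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def map_gene_set(gs: GeneSet, mapping: dict[str, str]) -> GeneSet:
    """Translate a gene set through an ortholog map, dropping unmapped ids."""
    mapped = list(dict.fromkeys(mapping[g] for g in gs.genes if g in mapping))
    if not mapped:
        raise ParseError(f"no gene of set {gs.name!r} maps through the ortholog table")
    return GeneSet(name=gs.name, genes=tuple(mapped), description=gs.description)
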