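"""Readers/writers for the external formats the pipeline touches, plus run configuration.

All genomic coordinates are 1-based inclusive (GFF3 convention).  Homology-hit
tables are the 12-column tab-separated BLAST/DIAMOND ``outfmt 6`` dialect with a
13th subject-taxon column::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore staxid
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxid",
]


@dataclass(frozen=True)
class GeneModel:
    """Structural summary of one gene, built from its longest isoform."""

    gene_id: str
    protein_length: int  # aa
    cds_length: int      # bp, summed CDS segments of the chosen isoform
    exon_count: int
    chromosome: str
    start: int           # 1-based inclusive
    end: int
    strand: str          # '+' or '-'

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"{self.gene_id}: cds_length must be positive")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.cds_length > 3 * self.protein_length + 3:
            raise ValueError(
                f"{self.gene_id}: cds_length {self.cds_length} inconsistent with "
                f"protein length {self.protein_length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class HomologyHit:
    """A single homology-search hit of a focal gene against a subject taxon."""

    query_gene: str
    subject_taxon: str
    bitscore: float
    evalue: float
    pairwise_distance: float = float("nan")  # caller-declared unit (subst/site or MY)

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be non-negative")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class RunConfig:
    """Every tunable threshold in the pipeline, with field defaults as used throughout.

    Cutoffs follow the conventions of the tools they stand in for: homology hits
    above ``evalue_cutoff`` are discarded, genes whose taxonomic representativeness
    falls strictly below ``representativeness_cutoff`` percent are excluded as
    putative contaminants/HGT, and an age call is confident only when the
    homology-detection-failure probability in the closest outgroup is below
    ``hdf_alpha``.
    """

    evalue_cutoff: float = 1e-5
    representativeness_cutoff: float = 30.0   # percent
    hdf_alpha: float = 0.05
    mcl_inflation: float = 2.0
    mcl_prune: float = 1e-5
    detection_threshold_bitscore: float = 30.0
    expressed_tpm_cutoff: float = 1.0
    broad_tissue_cutoff: int = 10
    tau_specific_cutoff: float = 0.8
    de_fdr: float = 0.05
    de_abs_lfc: float = 1.0
    soft_power: int = 8
    min_module_size: int = 30
    tree_cut_height: float = 0.25
    hub_kme: float = 0.7
    module_kme: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.representativeness_cutoff <= 100:
            raise ValueError("representativeness_cutoff is a percent")
        if not 0 <= self.hdf_alpha <= 1:
            raise ValueError("hdf_alpha is a probability")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must exceed 1")
        if not 0 <= self.tau_specific_cutoff <= 1:
            raise ValueError("tau_specific_cutoff must lie in [0,1]")
        if not 0 < self.de_fdr < 1:
            raise ValueError("de_fdr must lie in (0,1)")
        if self.soft_power < 1 or self.min_module_size < 2:
            raise ValueError("invalid network parameters")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON or YAML config file; keyword overrides win."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class GFF3Error(ValueError):
    """Raised for a malformed GFF3 feature hierarchy."""


def _isoform_sort_key(item: tuple[str, dict]) -> tuple[int, str]:
    tid, rec = item
    # longest summed CDS wins; ties break to the lexicographically smallest id
    return (-rec["cds_length"], tid)


def read_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Build one :class:`GeneModel` per gene from a GFF3 + protein FASTA pair.

    The representative isoform is the mRNA with the longest summed CDS length
    (ties broken by lexicographically smallest transcript id).  Isoforms present
    in the GFF3 but missing from the FASTA are skipped with a warning; a gene
    whose every isoform is missing is dropped.
    """
    proteins = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        isoforms: dict[str, dict] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_len = sum(f.end - f.start + 1 for f in db.children(mrna, featuretype="CDS"))
            exon_n = sum(1 for _ in db.children(mrna, featuretype="exon"))
            if cds_len == 0:
                raise GFF3Error(f"mRNA {mrna.id} of gene {gene.id} has no CDS features")
            if exon_n == 0:
                raise GFF3Error(f"mRNA {mrna.id} of gene {gene.id} has no exon features")
            if mrna.id not in proteins:
                logger.warning("isoform %s absent from FASTA; skipped", mrna.id)
                continue
            isoforms[mrna.id] = {"cds_length": cds_len, "exon_count": exon_n}
        if not isoforms:
            logger.warning("gene %s has no usable isoform; dropped", gene.id)
            continue
        tid, rec = sorted(isoforms.items(), key=_isoform_sort_key)[0]
        models.append(GeneModel(
            gene_id=gene.id,
            protein_length=proteins[tid],
            cds_length=rec["cds_length"],
            exon_count=rec["exon_count"],
            chromosome=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand,
        ))
    return models


def read_hit_table(path: str | Path, evalue_cutoff: float = 1e-5) -> list[HomologyHit]:
    """Parse a 13-column outfmt-6 hit table, dropping hits above the e-value cutoff."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                         dtype={"qseqid": str, "sseqid": str, "staxid": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=HIT_COLUMNS)
    if df.empty:
        logger.warning("hit table %s is empty", path)
        return []
    for col in ("evalue", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    keep = df["evalue"] <= evalue_cutoff
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d hits above e-value %.3g", path, n_dropped, evalue_cutoff)
    return [
        HomologyHit(query_gene=r.qseqid, subject_taxon=r.staxid,
                    bitscore=float(r.bitscore), evalue=float(r.evalue))
        for r in df[keep].itertuples()
    ]


def write_hit_table(path: str | Path, rows: Iterable[Mapping]) -> None:
    """Write hit rows (mappings with the outfmt-6 column names) as TSV."""
    df = pd.DataFrame(list(rows), columns=HIT_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_lineage_table(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV of (taxon, semicolon-joined root-to-tip lineage)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "lineage"], dtype=str)
    return {r.taxon: r.lineage.split(";") for r in df.itertuples()}


def write_lineage_table(path: str | Path, lineages: Mapping[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for taxon in lineages:
            fh.write(f"{taxon}\t{';'.join(lineages[taxon])}\n")


def read_ages_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of (stratum name, age in MYA)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["stratum", "age_mya"],
                     dtype={"stratum": str})
    return {r.stratum: float(r.age_mya) for r in df.itertuples()}


def write_ages_table(path: str | Path, ages: Mapping[str, float]) -> None:
    with open(path, "w") as fh:
        for name, age in ages.items():
            fh.write(f"{name}\t{age:g}\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV matrix (header row = sample ids, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df

def write_matrix(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample, tissue[, stage, condition]."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    return meta.set_index("sample")


def write_run_report(path: str | Path, config: RunConfig,
                     input_paths: Iterable[str | Path]) -> None:
    """Record seed, config hash and input checksums for reproducibility audits."""
    checksums = {}
    for p in sorted(str(p) for p in input_paths):
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        checksums[p] = h
    report = {
        "rng_seed": config.rng_seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "input_sha256": checksums,
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
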