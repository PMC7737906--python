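"""Input handling and linkage-disequilibrium estimation.

This module owns the data stores consumed by the gene-based tests: GWAS
summary statistics (per-variant z-scores), a haplotype/genotype reference
panel used to estimate LD, gene models with transcription start sites,
variant-level functional annotations (coding and UTR subclasses,
enhancer-to-gene confidence weights), and tissue-specific eQTL predictive
weight vectors.

Coordinates are 1-based inclusive throughout (VCF/GTF convention); distances
are in base pairs. Indels are matched by exact ref/alt strings; no
left-normalization is performed.
"""

from __future__ import annotations

import hashlib
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp as _logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SummaryStatTable",
    "HaplotypePanel",
    "LDMatrix",
    "GeneModel",
    "AnnotationStore",
    "TissueWeightMatrix",
    "HarmonizeReport",
    "LDProvider",
    "read_summary_stats",
    "harmonize_alleles",
    "compute_ld",
    "regularize_ld",
    "aggregate_enhancer_scores",
    "read_gene_models",
    "read_eqtl_weights",
    "read_enhancer_links",
    "read_coding_utr_annotations",
]

#: default ridge applied before eigendecompositions and quadratic-form
#: denominators; finite reference panels routinely yield singular LD matrices
DEFAULT_RIDGE_EPS = 1e-3

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class VariantKey(NamedTuple):
    """Identity of a bi-allelic variant: (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G SNPs cannot be oriented across strand conventions."""
        return _COMPLEMENT.get(self.ref) == self.alt


def _is_snp(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in _COMPLEMENT and alt in _COMPLEMENT


class FormatError(ValueError):
    """Raised for malformed or incomplete input files."""


@dataclass
class SummaryStatTable:
    """Per-variant GWAS association z-scores keyed by :class:`VariantKey`.

    ``df`` has columns chrom, pos, ref, alt, z, p and optionally n. The
    two-sided p-value is always derived from z as 2*Phi(-|z|).
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if "p" not in self.df.columns:
            self.df["p"] = 2.0 * norm.sf(np.abs(self.df["z"].to_numpy()))
        self._index = {
            VariantKey(str(c), int(p), r, a): i
            for i, (c, p, r, a) in enumerate(
                zip(self.df["chrom"], self.df["pos"], self.df["ref"], self.df["alt"])
            )
        }
        if len(self._index) != len(self.df):
            raise FormatError("duplicate variant keys in summary statistics")

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[VariantKey]:
        return list(self._index)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def z_for(self, keys: Sequence[VariantKey]) -> np.ndarray:
        idx = [self._index[k] for k in keys]
        return self.df["z"].to_numpy()[idx]

    def p_for(self, keys: Sequence[VariantKey]) -> np.ndarray:
        idx = [self._index[k] for k in keys]
        return self.df["p"].to_numpy()[idx]

    def subset(self, keys: Iterable[VariantKey]) -> "SummaryStatTable":
        idx = [self._index[k] for k in keys if k in self._index]
        return SummaryStatTable(self.df.iloc[idx].reset_index(drop=True))

    def to_file(self, path) -> None:
        out = self.df.rename(
            columns={"chrom": "CHROM", "pos": "POS", "ref": "REF", "alt": "ALT",
                     "z": "Z", "p": "PVAL", "n": "N"}
        )
        out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> SummaryStatTable:
    """Read tab-delimited GWAS summary statistics.

    Requires header columns CHROM, POS, REF, ALT and either Z or BETA+SE
    (z computed as beta/se). Rows with non-finite values are dropped and
    counted in ``n_dropped``. Gzip compression is inferred from the filename.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str}, comment="#")
    cols = set(df.columns)
    required = {"CHROM", "POS", "REF", "ALT"}
    if not required <= cols:
        raise FormatError(f"missing required columns: {sorted(required - cols)}")
    if "Z" in cols:
        z = pd.to_numeric(df["Z"], errors="coerce")
    elif {"BETA", "SE"} <= cols:
        beta = pd.to_numeric(df["BETA"], errors="coerce")
        se = pd.to_numeric(df["SE"], errors="coerce")
        se = se.where(se > 0)
        z = beta / se
    else:
        raise FormatError("need either a Z column or BETA and SE columns")
    out = pd.DataFrame(
        {
            "chrom": df["CHROM"].astype(str),
            "pos": pd.to_numeric(df["POS"], errors="coerce"),
            "ref": df["REF"].astype(str),
            "alt": df["ALT"].astype(str),
            "z": z,
        }
    )
    if "N" in cols:
        out["n"] = pd.to_numeric(df["N"], errors="coerce")
    keep = np.isfinite(out["z"].to_numpy(dtype=float)) & np.isfinite(
        out["pos"].to_numpy(dtype=float)
    )
    n_dropped = int((~keep).sum())
    out = out[keep].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    dup = out.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        row = out[dup].iloc[0]
        raise FormatError(
            f"duplicate variant {row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
        )
    if n_dropped:
        logger.info("read_summary_stats: dropped %d rows with non-finite values", n_dropped)
    return SummaryStatTable(out, n_dropped=n_dropped)


@dataclass
class HaplotypePanel:
    """LD reference panel: a (samples x variants) dosage matrix.

    Values are {0,1} per haplotype or {0,1,2} per genotype; either works for
    Pearson-correlation LD. Columns must be polymorphic after filtering.
    """

    dosages: np.ndarray
    variants: list[VariantKey]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage matrix and variant index disagree")
        self._index = {v: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variants in panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def column(self, key: VariantKey) -> np.ndarray:
        return self.dosages[:, self._index[key]]

    def columns(self, keys: Sequence[VariantKey]) -> np.ndarray:
        idx = [self._index[k] for k in keys]
        return self.dosages[:, idx]

    def frequencies(self, keys: Sequence[VariantKey]) -> np.ndarray:
        """Alt-allele frequency per variant (dosage mean / max dosage)."""
        cols = self.columns(keys).astype(float)
        return cols.mean(axis=0) / max(1.0, float(cols.max(initial=1)))

    def lookup_position(self, chrom: str, pos: int) -> list[VariantKey]:
        # small panels only; position index built lazily
        if not hasattr(self, "_pos_index"):
            pos_index: dict[tuple[str, int], list[VariantKey]] = {}
            for v in self.variants:
                pos_index.setdefault((v.chrom, v.pos), []).append(v)
            self._pos_index = pos_index
        return self._pos_index.get((chrom, pos), [])

    @classmethod
    def from_vcf(cls, path, drop_monomorphic: bool = True) -> "HaplotypePanel":
        """Load haplotypes (phased GT) or genotype dosages from a VCF/BCF."""
        import pysam

        variants: list[VariantKey] = []
        cols: list[np.ndarray] = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                gts = []
                phased = True
                for sample in rec.samples.values():
                    gt = sample["GT"]
                    if any(a is None for a in gt):
                        gts = []
                        break
                    phased = phased and sample.phased
                    gts.append(gt)
                if not gts:
                    continue
                arr = np.asarray(gts, dtype=np.int8)
                col = arr.reshape(-1) if phased else arr.sum(axis=1)
                if drop_monomorphic and (col.min() == col.max()):
                    continue
                variants.append(
                    VariantKey(str(rec.chrom), int(rec.pos), str(rec.ref), str(rec.alts[0]))
                )
                cols.append(col)
        if not cols:
            raise FormatError(f"no usable variant records in {path}")
        return cls(np.column_stack(cols), variants)

    def to_vcf(self, path) -> None:
        """Write the panel as a phased-diploid VCF (requires even haplotype count)."""
        import pysam

        if self.n_samples % 2 != 0:
            raise ValueError("need an even number of haplotypes to write diploid VCF")
        n_dip = self.n_samples // 2
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        chroms = []
        for v in self.variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            header.contigs.add(c, length=max(v.pos for v in self.variants if v.chrom == c) + 10**6)
        for i in range(n_dip):
            header.add_sample(f"S{i:04d}")
        order = sorted(range(len(self.variants)), key=lambda i: (chroms.index(self.variants[i].chrom), self.variants[i].pos))
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for i in order:
                v = self.variants[i]
                rec = vf.new_record(
                    contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                    alleles=(v.ref, v.alt),
                )
                col = self.dosages[:, i]
                for j in range(n_dip):
                    rec.samples[j]["GT"] = (int(col[2 * j]), int(col[2 * j + 1]))
                    rec.samples[j].phased = True
                vf.write(rec)


@dataclass
class HarmonizeReport:
    n_matched: int = 0
    n_flipped: int = 0
    n_ambiguous_dropped: int = 0
    n_mismatch: int = 0
    n_unmatched: int = 0


def harmonize_alleles(
    stats: SummaryStatTable,
    panel: HaplotypePanel,
    ambiguous: str = "drop",
) -> tuple[SummaryStatTable, HarmonizeReport]:
    """Match summary statistics against the reference panel on (chrom, pos).

    If ref/alt are swapped relative to the panel the z sign is flipped.
    Strand-ambiguous A/T and C/G SNPs are dropped by default (``ambiguous=
    'drop'``); ``ambiguous='keep'`` retains them, matching alleles as
    written. Unmatched variants are dropped with counts in the report.
    Idempotent on already-harmonized input.
    """
    if ambiguous not in {"drop", "keep"}:
        raise ValueError("ambiguous must be 'drop' or 'keep'")
    report = HarmonizeReport()
    rows = []
    arr = stats.df
    for i in range(len(arr)):
        key = VariantKey(
            str(arr["chrom"].iat[i]), int(arr["pos"].iat[i]),
            str(arr["ref"].iat[i]), str(arr["alt"].iat[i]),
        )
        z = float(arr["z"].iat[i])
        if _is_snp(key.ref, key.alt) and key.is_strand_ambiguous() and ambiguous == "drop":
            report.n_ambiguous_dropped += 1
            continue
        candidates = panel.lookup_position(key.chrom, key.pos)
        if not candidates:
            report.n_unmatched += 1
            continue
        matched = None
        flipped = False
        for cand in candidates:
            if (cand.ref, cand.alt) == (key.ref, key.alt):
                matched, flipped = cand, False
                break
            if (cand.ref, cand.alt) == (key.alt, key.ref):
                matched, flipped = cand, True
                break
            if _is_snp(key.ref, key.alt) and _is_snp(cand.ref, cand.alt):
                flip_ref = _COMPLEMENT[key.ref]
                flip_alt = _COMPLEMENT[key.alt]
                if (cand.ref, cand.alt) == (flip_ref, flip_alt):
                    matched, flipped = cand, False
                    break
                if (cand.ref, cand.alt) == (flip_alt, flip_ref):
                    matched, flipped = cand, True
                    break
        if matched is None:
            report.n_mismatch += 1
            continue
        report.n_matched += 1
        if flipped:
            report.n_flipped += 1
            z = -z
        row = {"chrom": matched.chrom, "pos": matched.pos, "ref": matched.ref,
               "alt": matched.alt, "z": z}
        if "n" in arr.columns:
            row["n"] = arr["n"].iat[i]
        rows.append(row)
    if not rows:
        raise FormatError("no variants in common between summary stats and panel")
    return SummaryStatTable(pd.DataFrame(rows)), report


@dataclass
class LDMatrix:
    """Symmetric unit-diagonal correlation matrix over an ordered variant set."""

    R: np.ndarray
    variants: tuple[VariantKey, ...] = ()

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        self.variants = tuple(self.variants)
        if self.variants and len(self.variants) != self.R.shape[0]:
            raise ValueError("variant index length does not match R")

    @property
    def m(self) -> int:
        return self.R.shape[0]

    def validate(self, tol: float = 1e-8) -> None:
        if not np.allclose(self.R, self.R.T, atol=tol):
            raise ValueError("R is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=tol):
            raise ValueError("R does not have unit diagonal")


def compute_ld(panel: HaplotypePanel, variants: Sequence[VariantKey]) -> LDMatrix:
    """Pearson-correlation LD over the given variants, from panel dosages."""
    cols = panel.columns(variants).astype(float)
    sd = cols.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"monomorphic variant in LD computation: {variants[bad[0]]}")
    R = np.corrcoef(cols, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(R, tuple(variants))


def regularize_ld(ld: LDMatrix, eps: float = DEFAULT_RIDGE_EPS) -> LDMatrix:
    """Ridge-regularize: (1-eps)*R + eps*I. Keeps the unit diagonal and
    bounds the smallest eigenvalue below by eps + (1-eps)*lambda_min(R)."""
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must lie in [0, 1)")
    if eps == 0.0:
        return ld
    R = (1.0 - eps) * ld.R + eps * np.eye(ld.m)
    return LDMatrix(R, ld.variants)


def aggregate_enhancer_scores(scores: Sequence[float]) -> float:
    """Soft maximum (LogSumExp) of tissue/cell-type enhancer confidence scores."""
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise ValueError("aggregate_enhancer_scores requires at least one score")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite enhancer score")
    return float(_logsumexp(s))


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS: TSS = start on '+', end on '-'."""

    gene: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand for {self.gene}: {self.strand}")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def body_distance(self, pos: int) -> int:
        """bp distance from a position to the gene body (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read gene models from a 5-column TSV (gene, chrom, strand, start, end)
    or a GTF file (``gene`` features; parsed via gffutils)."""
    path = str(path)
    if path.endswith((".gtf", ".gtf.gz", ".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        out = {}
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("gene_id", [feat.id])[0]
            out[gid] = GeneModel(gid, str(feat.seqid), feat.strand, feat.start, feat.end)
        if not out:
            raise FormatError(f"no gene features in {path}")
        return out
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    required = {"gene", "chrom", "strand", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"gene model TSV missing columns {sorted(required - set(df.columns))}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.gene)] = GeneModel(
            str(row.gene), str(row.chrom), str(row.strand), int(row.start), int(row.end)
        )
    return out


def write_gene_models(models: Mapping[str, GeneModel], path) -> None:
    pd.DataFrame(
        [
            {"gene": g.gene, "chrom": g.chrom, "strand": g.strand,
             "start": g.start, "end": g.end}
            for g in models.values()
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationStore:
    """Variant-to-gene annotation records.

    One row per (variant, gene, class, subclass): class is one of
    {coding, utr, enhancer}; subclass is the coding consequence (missense,
    nonsense, synonymous, ...), the UTR side (3utr/5utr), or the enhancer id.
    ``weight`` carries the enhancer-to-gene confidence weight (1.0 for
    coding/UTR rows).
    """

    df: pd.DataFrame

    COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "cls", "subclass", "weight")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise FormatError(f"annotation store missing columns {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        if self.df.duplicated(subset=["chrom", "pos", "ref", "alt", "gene", "cls", "subclass"]).any():
            raise FormatError("duplicate (variant, gene, class, subclass) annotation record")
        if (self.df["weight"] < 0).any():
            raise FormatError("negative annotation weight")

    def __len__(self) -> int:
        return len(self.df)

    def for_gene(self, gene: str, cls: str | None = None) -> pd.DataFrame:
        sel = self.df["gene"] == gene
        if cls is not None:
            sel &= self.df["cls"] == cls
        return self.df[sel]

    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def variant_keys(self, rows: pd.DataFrame | None = None) -> list[VariantKey]:
        d = self.df if rows is None else rows
        return [
            VariantKey(str(c), int(p), r, a)
            for c, p, r, a in zip(d["chrom"], d["pos"], d["ref"], d["alt"])
        ]

    def restrict_to(self, stats: SummaryStatTable) -> "AnnotationStore":
        keep = [k in stats for k in self.variant_keys()]
        n_drop = len(keep) - sum(keep)
        if n_drop:
            logger.info("annotation store: dropped %d records not in summary stats", n_drop)
        return AnnotationStore(self.df[keep].reset_index(drop=True))

    def to_file(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path) -> "AnnotationStore":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#"))


def read_coding_utr_annotations(path) -> AnnotationStore:
    """Read coding/UTR annotations: TSV (CHROM, POS, REF, ALT, gene, subclass).

    Subclasses 3utr/5utr are stored under class 'utr'; everything else under
    'coding'. Weight is 1 for these classes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str}, comment="#")
    required = {"CHROM", "POS", "REF", "ALT", "gene", "subclass"}
    if not required <= set(df.columns):
        raise FormatError(f"annotation TSV missing columns {sorted(required - set(df.columns))}")
    sub = df["subclass"].astype(str).str.lower()
    out = pd.DataFrame(
        {
            "chrom": df["CHROM"].astype(str),
            "pos": df["POS"].astype(int),
            "ref": df["REF"].astype(str),
            "alt": df["ALT"].astype(str),
            "gene": df["gene"].astype(str),
            "cls": np.where(sub.isin(["3utr", "5utr"]), "utr", "coding"),
            "subclass": sub,
            "weight": 1.0,
        }
    )
    return AnnotationStore(out)


def read_enhancer_links(path, panel: HaplotypePanel) -> AnnotationStore:
    """Read enhancer-to-gene links and attach panel variants within each element.

    TSV columns: enhancer, chrom, start, end, gene, tissue (or 'global'),
    score. Tissue-specific scores for the same (enhancer, gene) pair are
    aggregated with the LogSumExp soft maximum into a single confidence
    weight; 'global' scores pass through unchanged when they are the only
    record. Elements containing no panel variant are dropped (counted).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    required = {"enhancer", "chrom", "start", "end", "gene", "tissue", "score"}
    if not required <= set(df.columns):
        raise FormatError(f"enhancer TSV missing columns {sorted(required - set(df.columns))}")
    rows = []
    n_empty = 0
    grouped = df.groupby(["enhancer", "gene"], sort=True)
    for (enh, gene), grp in grouped:
        weight = aggregate_enhancer_scores(grp["score"].to_list())
        chrom = str(grp["chrom"].iloc[0])
        start, end = int(grp["start"].iloc[0]), int(grp["end"].iloc[0])
        member = [
            v for v in panel.variants
            if v.chrom == chrom and start <= v.pos <= end
        ]
        if not member:
            n_empty += 1
            continue
        for v in member:
            rows.append(
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "gene": str(gene), "cls": "enhancer", "subclass": str(enh),
                 "weight": weight}
            )
    if n_empty:
        logger.info("enhancer links: dropped %d elements with no panel variants", n_empty)
    if not rows:
        raise FormatError("no enhancer elements resolved against the panel")
    return AnnotationStore(pd.DataFrame(rows))


@dataclass
class TissueWeightMatrix:
    """Signed eQTL predictive weight vectors b_{kt} per (gene, tissue)."""

    entries: dict[tuple[str, str], tuple[list[VariantKey], np.ndarray]] = field(
        default_factory=dict
    )

    def add(self, gene: str, tissue: str, variants: Sequence[VariantKey], weights) -> None:
        w = np.asarray(weights, dtype=float)
        if len(variants) != w.size:
            raise ValueError("weights and variants disagree in length")
        if not np.any(w != 0):
            raise ValueError(f"all-zero weight vector for ({gene}, {tissue})")
        self.entries[(gene, tissue)] = (list(variants), w)

    def tissues_for(self, gene: str) -> list[str]:
        return sorted(t for (g, t) in self.entries if g == gene)

    def genes(self) -> list[str]:
        return sorted({g for (g, _) in self.entries})

    def get(self, gene: str, tissue: str) -> tuple[list[VariantKey], np.ndarray]:
        return self.entries[(gene, tissue)]

    def __len__(self) -> int:
        return len(self.entries)

    def to_file(self, path) -> None:
        rows = []
        for (gene, tissue), (variants, w) in sorted(self.entries.items()):
            for v, wi in zip(variants, w):
                rows.append(
                    {"gene": gene, "tissue": tissue, "CHROM": v.chrom, "POS": v.pos,
                     "REF": v.ref, "ALT": v.alt, "weight": wi}
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path) -> "TissueWeightMatrix":
        return read_eqtl_weights(path)


def read_eqtl_weights(path, panel: HaplotypePanel | None = None) -> TissueWeightMatrix:
    """Read tissue-specific eQTL weights: TSV (gene, tissue, CHROM, POS, REF,
    ALT, weight). When a panel is given, weight variants absent from it are
    dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str}, comment="#")
    required = {"gene", "tissue", "CHROM", "POS", "REF", "ALT", "weight"}
    if not required <= set(df.columns):
        raise FormatError(f"eQTL weight TSV missing columns {sorted(required - set(df.columns))}")
    out = TissueWeightMatrix()
    n_dropped = 0
    for (gene, tissue), grp in df.groupby(["gene", "tissue"], sort=True):
        variants, weights = [], []
        for row in grp.itertuples(index=False):
            key = VariantKey(str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))
            if panel is not None and key not in panel:
                n_dropped += 1
                continue
            variants.append(key)
            weights.append(float(row.weight))
        if variants and any(w != 0 for w in weights):
            out.add(str(gene), str(tissue), variants, weights)
    if n_dropped:
        logger.info("eQTL weights: dropped %d unresolvable variants", n_dropped)
    if not len(out):
        raise FormatError("no usable eQTL weight vectors")
    return out


class LDProvider:
    """On-demand LD with ridge regularization and an LRU cache.

    LD is computed per variant set, never genome-wide; cache keys hash the
    ordered variant tuple.
    """

    def __init__(self, panel: HaplotypePanel, eps: float = DEFAULT_RIDGE_EPS,
                 cache_size: int = 64):
        self.panel = panel
        self.eps = eps
        self._cache: OrderedDict[str, LDMatrix] = OrderedDict()
        self._cache_size = cache_size

    @staticmethod
    def _key(variants: Sequence[VariantKey]) -> str:
        h = hashlib.sha1()
        for v in variants:
            h.update(f"{v.chrom}:{v.pos}:{v.ref}:{v.alt};".encode())
        return h.hexdigest()

    def ld(self, variants: Sequence[VariantKey], regularized: bool = True) -> LDMatrix:
        key = self._key(variants) + ("R" if regularized else "")
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        raw = compute_ld(self.panel, variants)
        result = regularize_ld(raw, self.eps) if regularized else raw
        self._cache[key] = result
        if len(self._cache) > self._cache_size:
            self._cache.popitem(last=False)
        return result
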