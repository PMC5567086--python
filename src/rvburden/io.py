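"""Readers and writers for the pipeline's external formats.

Formats handled here: multi-sample VCF (via pysam), per-variant annotation
tables (TSV), in-house panel variant lists, gene-set collections with a
declared background universe, directed gene-interaction edge lists, and
result tables.  Everything downstream works on the in-memory containers
defined in this module.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("rvburden")

__all__ = [
    "InputError",
    "VcfParseError",
    "VariantKey",
    "AnnotatedVariant",
    "CohortGenotypes",
    "GeneSetCollection",
    "InteractionEdgeList",
    "CONSEQUENCES",
    "read_vcf",
    "read_annotations",
    "read_panel",
    "read_gene_sets",
    "read_edge_list",
    "write_table",
    "read_table",
]


class InputError(ValueError):
    """Raised when an input file violates its declared contract."""


class VcfParseError(InputError):
    """Raised when a VCF cannot be parsed; message names the offending site."""


#: Consequence vocabulary.  Unknown labels collapse to "other".
CONSEQUENCES = frozenset(
    {
        "nonsense",
        "splice_site",
        "missense",
        "frameshift_indel",
        "inframe_indel",
        "synonymous",
        "other",
    }
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

# carriage codes in CohortGenotypes.carriage
NON_CARRIER = 0
HET = 1
HOM = 2
MISSING = -1


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a single decomposed variant: (chrom, pos, ref, alt).

    Coordinates are 1-based as in VCF.  Multi-allelic records are
    decomposed upstream so every key carries exactly one alternate allele.
    Shared REF/ALT suffixes are trimmed so that the same event written two
    ways compares equal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele):
                raise InputError(
                    f"{name} allele {allele!r} at {self.chrom}:{self.pos} "
                    "must be a non-empty A/C/G/T string"
                )
        if self.ref == self.alt:
            raise InputError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def make_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a canonical VariantKey, trimming shared REF/ALT suffixes."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return VariantKey(str(chrom), int(pos), ref, alt)


@dataclass
class AnnotatedVariant:
    """One variant with its gene, consequence class, population allele
    frequencies and the two deleteriousness-predictor calls.

    Frequencies and predictor fields may be missing (None); missing data is
    interpreted by the filter layer, not here.
    """

    key: VariantKey
    gene: str
    consequence: str
    af_1000g: float | None = None
    af_exac: float | None = None
    mt_score: float | None = None
    mt_pred: str | None = None  # "D" (disease-causing) or "N"
    rsvm_score: float | None = None
    rsvm_pred: str | None = None  # "D" (damaging) or "T" (tolerated)
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            self.consequence = "other"
        for name in ("af_1000g", "af_exac"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InputError(
                    f"{name}={v} outside [0,1] for {self.key.chrom}:{self.key.pos}"
                )


@dataclass
class CohortGenotypes:
    """Sample-by-variant carrier matrix with case/control phenotype labels.

    ``carriage[i, j]`` holds the coding of sample i at variant j:
    0 non-carrier, 1 het, 2 hom, -1 missing genotype.
    """

    samples: list[str]
    phenotype: dict[str, str]  # sample -> "case" | "control"
    variants: list[VariantKey]
    carriage: np.ndarray  # (n_samples, n_variants) int8

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.phenotype]
        if missing:
            raise InputError(f"samples without phenotype: {missing[:5]}")
        bad = set(self.phenotype.values()) - {"case", "control"}
        if bad:
            raise InputError(f"unknown phenotype labels: {sorted(bad)}")
        self.carriage = np.asarray(self.carriage, dtype=np.int8)
        if self.carriage.shape != (len(self.samples), len(self.variants)):
            raise InputError(
                f"carriage shape {self.carriage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([self.phenotype[s] == "case" for s in self.samples])

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return len(self.samples) - self.n_cases

    def subset_variants(self, keys: list[VariantKey]) -> "CohortGenotypes":
        index = {k: j for j, k in enumerate(self.variants)}
        cols = [index[k] for k in keys]
        return CohortGenotypes(
            samples=self.samples,
            phenotype=self.phenotype,
            variants=list(keys),
            carriage=self.carriage[:, cols],
        )


@dataclass
class GeneSetCollection:
    """Flat gene sets (term_id -> name + member genes) over a background
    gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise InputError(f"term {term_id} has zero genes")
            stray = genes - self.background
            if stray:
                raise InputError(
                    f"term {term_id} members outside background: {sorted(stray)[:5]}"
                )


@dataclass
class InteractionEdgeList:
    """Directed gene-interaction edges (source, target, relation label).

    Self-loops are dropped and duplicate (source, target) pairs collapsed at
    construction.
    """

    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        n_loops = 0
        for src, dst, rel in self.edges:
            if src == dst:
                n_loops += 1
                continue
            seen.setdefault((src, dst), rel)
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        self.edges = [(s, t, r) for (s, t), r in seen.items()]

    def pairs(self) -> list[tuple[str, str]]:
        return [(s, t) for s, t, _ in self.edges]


# ---------------------------------------------------------------------------
# VCF


def _decompose_record(rec) -> list[tuple[VariantKey, int]]:
    """One (key, alt_index) per alternate allele, skipping symbolic alleles."""
    out = []
    for i, alt in enumerate(rec.alts or ()):
        if alt is None or not _ALLELE_RE.match(alt.upper()):
            continue  # symbolic / spanning-deletion alleles carry no key
        out.append((make_key(rec.chrom, rec.pos, rec.ref, alt), i + 1))
    return out


def read_vcf(path: str, phenotype: dict[str, str] | None = None) -> CohortGenotypes:
    """Read a multi-sample VCF into a carrier matrix.

    Multi-allelic sites are decomposed into one variant per alternate
    allele; a genotype with >= 1 copy of that allele codes het (1 copy) or
    hom (2 copies); a fully missing genotype codes -1.  ``phenotype`` maps
    sample name to "case"/"control"; if omitted, every sample is labelled
    "case" and must be relabelled before burden testing.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise InputError(f"VCF {path} has no sample columns")

    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    last = "header"
    try:
        for rec in vcf:
            last = f"{rec.chrom}:{rec.pos}"
            for key, alt_idx in _decompose_record(rec):
                col = np.zeros(len(samples), dtype=np.int8)
                for i, sample in enumerate(samples):
                    gt = rec.samples[sample].get("GT")
                    alleles = [a for a in (gt or ()) if a is not None]
                    if not alleles:
                        col[i] = MISSING
                    else:
                        copies = sum(a == alt_idx for a in alleles)
                        col[i] = min(copies, 2)
                keys.append(key)
                columns.append(col)
    except (OSError, ValueError) as exc:
        raise VcfParseError(
            f"malformed VCF {path} after record {last}: {exc}"
        ) from exc

    carriage = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    phenotype = phenotype or {s: "case" for s in samples}
    return CohortGenotypes(samples, dict(phenotype), keys, carriage)


# ---------------------------------------------------------------------------
# Annotation table

ANNOTATION_COLUMNS = [
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "GENE",
    "CONSEQUENCE",
    "AF_1000G_EAS",
    "AF_EXAC_EAS",
    "MT_SCORE",
    "MT_PRED",
    "RSVM_SCORE",
    "RSVM_PRED",
    "PROTEIN_CHANGE",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return str(value)


def read_annotations(path: str) -> dict[VariantKey, AnnotatedVariant]:
    """Read the per-variant annotation TSV ("." = missing) keyed by variant."""
    df = pd.read_csv(
        path, sep="\t", comment="#", na_values=["."], dtype={"CHROM": str}
    )
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"annotation table {path} lacks columns {missing_cols}")

    out: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        key = make_key(row.CHROM, row.POS, row.REF, row.ALT)
        if key in out:
            raise InputError(f"duplicate annotation row for {key}")
        out[key] = AnnotatedVariant(
            key=key,
            gene=_opt_str(row.GENE) or "",
            consequence=_opt_str(row.CONSEQUENCE) or "other",
            af_1000g=_opt_float(row.AF_1000G_EAS),
            af_exac=_opt_float(row.AF_EXAC_EAS),
            mt_score=_opt_float(row.MT_SCORE),
            mt_pred=_opt_str(row.MT_PRED),
            rsvm_score=_opt_float(row.RSVM_SCORE),
            rsvm_pred=_opt_str(row.RSVM_PRED),
            protein_change=_opt_str(row.PROTEIN_CHANGE),
        )
    return out


def read_panel(path: str) -> set[VariantKey]:
    """Read an in-house panel variant list (TSV: CHROM POS REF ALT)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHROM": str})
    for col in ("CHROM", "POS", "REF", "ALT"):
        if col not in df.columns:
            raise InputError(f"panel file {path} lacks column {col}")
    return {
        make_key(r.CHROM, r.POS, r.REF, r.ALT) for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Gene sets / edges


def read_gene_sets(terms_path: str, background_path: str) -> GeneSetCollection:
    """Read gene sets (TSV: TERM_ID, TERM_NAME, comma-separated GENES) and a
    background universe file (one gene symbol per line)."""
    with open(background_path) as fh:
        background = frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )
    if not background:
        raise InputError(f"background file {background_path} is empty")

    df = pd.read_csv(path_or_buf := terms_path, sep="\t", comment="#", dtype=str)
    for col in ("TERM_ID", "TERM_NAME", "GENES"):
        if col not in df.columns:
            raise InputError(f"gene-set file {path_or_buf} lacks column {col}")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for row in df.itertuples(index=False):
        genes = frozenset(g.strip() for g in str(row.GENES).split(",") if g.strip())
        if not genes:
            raise InputError(f"term {row.TERM_ID} has zero genes")
        terms[str(row.TERM_ID)] = (str(row.TERM_NAME), genes)
    return GeneSetCollection(terms=terms, background=background)


def read_edge_list(path: str) -> InteractionEdgeList:
    """Read a directed interaction edge list (TSV: SOURCE, TARGET, RELATION)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("SOURCE", "TARGET"):
        if col not in df.columns:
            raise InputError(f"edge list {path} lacks column {col}")
    rel = df["RELATION"] if "RELATION" in df.columns else pd.Series(
        ["interaction"] * len(df)
    )
    edges = [
        (str(s), str(t), str(r))
        for s, t, r in zip(df["SOURCE"], df["TARGET"], rel)
    ]
    return InteractionEdgeList(edges=edges)


# ---------------------------------------------------------------------------
# Result tables

from . import __version__ as _version  # noqa: E402  (cycle-free: defined first)


def config_hash(config: dict) -> str:
    """Short stable hash of a flat configuration mapping."""
    canonical = ";".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str, config: dict | None = None) -> None:
    """Write a result table as TSV with a commented provenance header.

    Floats are written at full precision (repr) so that a round-trip
    re-read reproduces values to better than 1e-12.
    """
    with open(path, "w") as fh:
        fh.write(f"# rvburden {_version} config_hash={config_hash(config or {})}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path: str) -> pd.DataFrame:
    """Re-read a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
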