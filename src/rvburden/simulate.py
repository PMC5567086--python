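"""Truth-labelled synthetic cohorts for exercising the whole pipeline.

The generator emulates the study design this pipeline targets: a small
case series (13 cases) screened against ~100 controls, with rare
background variation (MAF < 1%), a minority of common contaminant
variants, imperfect dual-predictor deleteriousness calls, an in-house
panel assembled from control-observed variants, flat gene-set terms with
one optionally planted enriched term, and a directed interaction edge
list.  Every stochastic choice flows from a single seeded generator, so a
fixed seed reproduces byte-identical files.

A planted burden gene carries damaging variants at a configured
case-carrier probability (default 0.25 vs 0.0 in controls — three
expected carriers among 13 cases, the regime of the worked example).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AnnotatedVariant,
    CohortGenotypes,
    GeneSetCollection,
    InputError,
    InteractionEdgeList,
    VariantKey,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort_data",
    "simulate_cohort",
    "simulate_gene_sets",
    "simulate_mutated_genes",
    "simulate_edges",
    "simulate_null_tables",
]

_BASES = np.array(list("ACGT"))

# consequence mix for background SNVs (roughly 2:1 nonsynonymous:synonymous,
# with small nonsense/splice fractions, as in rare exonic variation)
_SNV_CONSEQUENCES = ["missense", "synonymous", "nonsense", "splice_site", "other"]
_SNV_WEIGHTS = [0.60, 0.25, 0.05, 0.05, 0.05]
_INDEL_CONSEQUENCES = ["frameshift_indel", "inframe_indel"]
_INDEL_WEIGHTS = [0.7, 0.3]


@dataclass
class SimConfig:
    """Generator settings; defaults encode the emulated study design."""

    n_cases: int = 13
    n_controls: int = 100
    n_genes: int = 500
    variants_per_gene: float = 2.0  # mean of 1 + Poisson(mean - 1)
    background_carrier_prob: float = 0.01
    planted_genes: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("GENE0001", 0.25, 0.0)]
    )
    rare_af_range: tuple[float, float] = (1e-5, 0.009)
    common_contaminant_frac: float = 0.1
    predictor_concordance: float = 0.9  # P(D/D | truly deleterious)
    predictor_false_pos: float = 0.05  # P(D/D | benign)
    deleterious_frac: float = 0.3  # P(background variant truly deleterious)
    missing_af_prob: float = 0.3  # P(a rare variant is absent from a panel)
    indel_frac: float = 0.0  # variants drawn as indels instead of SNVs
    panel_overlap_frac: float = 1.0  # control-observed variants copied to panel
    n_terms: int = 50
    planted_term: tuple[str, float] = ("TERM0001", 6.0)  # (term_id, odds)
    planted_term_size: int = 40
    list_baseline_prob: float = 0.15  # P(background gene enters mutated list)
    edge_density: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_genes < 1:
            raise InputError("n_cases, n_controls and n_genes must be >= 1")
        for name in (
            "background_carrier_prob",
            "common_contaminant_frac",
            "predictor_concordance",
            "predictor_false_pos",
            "deleterious_frac",
            "missing_af_prob",
            "indel_frac",
            "panel_overlap_frac",
            "list_baseline_prob",
            "edge_density",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v} outside [0,1]")
        for gene, p_case, p_ctrl in self.planted_genes:
            if not (0.0 <= p_case <= 1.0 and 0.0 <= p_ctrl <= 1.0):
                raise InputError(f"planted carrier probs for {gene} outside [0,1]")
        if self.variants_per_gene < 1:
            raise InputError("variants_per_gene mean must be >= 1")

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class SimTruth:
    """Ground truth for recovery tests, consistent with the emitted files."""

    planted_genes: list[tuple[str, float, float]]
    realized_carriers: dict[str, tuple[int, int]]  # gene -> (case, control) carriers
    variant_flags: dict[VariantKey, dict]  # deleterious / rare / in_panel / gene
    planted_term: str | None = None


def _draw_variant_count(rng: np.random.Generator, mean: float) -> int:
    # shifted Poisson guarantees every gene owns >= 1 variant to assign
    return 1 + int(rng.poisson(mean - 1.0))


def _predictor_calls(
    rng: np.random.Generator, deleterious: bool, cfg: SimConfig
) -> tuple[float, str, float, str]:
    p_dd = cfg.predictor_concordance if deleterious else cfg.predictor_false_pos
    if rng.random() < p_dd:
        mt_pred, rsvm_pred = "D", "D"
    else:
        # discordant or doubly benign call
        mt_pred = "D" if rng.random() < 0.3 else "N"
        rsvm_pred = "T" if mt_pred == "D" else ("D" if rng.random() < 0.3 else "T")
    mt_score = rng.uniform(0.9, 1.0) if mt_pred == "D" else rng.uniform(0.0, 0.6)
    rsvm_score = rng.uniform(0.1, 1.0) if rsvm_pred == "D" else rng.uniform(-1.0, 0.0)
    return float(mt_score), mt_pred, float(rsvm_score), rsvm_pred


def _draw_afs(
    rng: np.random.Generator, cfg: SimConfig, contaminant: bool
) -> tuple[float | None, float | None]:
    if contaminant:
        af = float(rng.uniform(0.02, 0.2))
        return af, float(np.clip(af * rng.uniform(0.5, 1.5), 0.011, 0.5))
    lo, hi = cfg.rare_af_range
    out = []
    for _ in range(2):
        if rng.random() < cfg.missing_af_prob:
            out.append(None)  # "novel": unseen in the reference panel
        else:
            out.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return out[0], out[1]


def simulate_cohort_data(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CohortGenotypes, dict[VariantKey, AnnotatedVariant], set[VariantKey], SimTruth]:
    """Generate the cohort in memory (genotypes, annotations, panel, truth)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = cfg.gene_names()
    planted = {g: (pc, pq) for g, pc, pq in cfg.planted_genes}
    unknown = set(planted) - set(genes)
    if unknown:
        raise InputError(f"planted genes not in universe: {sorted(unknown)}")

    samples = [f"CASE{i + 1:03d}" for i in range(cfg.n_cases)] + [
        f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)
    ]
    phenotype = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    n_samples = len(samples)
    case_mask = np.array([phenotype[s] == "case" for s in samples])

    keys: list[VariantKey] = []
    annotations: dict[VariantKey, AnnotatedVariant] = {}
    columns: list[np.ndarray] = []
    flags: dict[VariantKey, dict] = {}
    realized: dict[str, tuple[int, int]] = {}

    for gi, gene in enumerate(genes):
        n_var = _draw_variant_count(rng, cfg.variants_per_gene)
        base_pos = gi * 10_000 + 1
        offsets = rng.choice(9_000, size=n_var, replace=False)
        offsets.sort()
        gene_planted = gene in planted

        gene_keys = []
        for vi in range(n_var):
            pos = int(base_pos + offsets[vi])
            is_indel = (not gene_planted) and rng.random() < cfg.indel_frac
            if is_indel:
                ref_len, alt_len = (1 + int(rng.integers(1, 4)), 1)
                if rng.random() < 0.5:
                    ref_len, alt_len = alt_len, ref_len
                anchor = str(rng.choice(_BASES))
                extra = "".join(rng.choice(_BASES, size=max(ref_len, alt_len) - 1))
                ref = anchor + extra[: ref_len - 1]
                alt = anchor + extra[: alt_len - 1]
                # avoid a shared suffix collapsing ref == alt
                if ref == alt:
                    ref = anchor + "A" if alt == anchor else ref
                consequence = str(
                    rng.choice(_INDEL_CONSEQUENCES, p=_INDEL_WEIGHTS)
                )
            else:
                ref = str(rng.choice(_BASES))
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                consequence = (
                    "missense"
                    if gene_planted
                    else str(rng.choice(_SNV_CONSEQUENCES, p=_SNV_WEIGHTS))
                )
            key = VariantKey("chrS", pos, ref, alt)
            deleterious = (
                True if gene_planted else bool(rng.random() < cfg.deleterious_frac)
            )
            contaminant = (
                False if gene_planted else bool(rng.random() < cfg.common_contaminant_frac)
            )
            af1, af2 = _draw_afs(rng, cfg, contaminant)
            mt_s, mt_p, rs_s, rs_p = _predictor_calls(rng, deleterious, cfg)
            annotations[key] = AnnotatedVariant(
                key=key,
                gene=gene,
                consequence=consequence,
                af_1000g=af1,
                af_exac=af2,
                mt_score=mt_s,
                mt_pred=mt_p,
                rsvm_score=rs_s,
                rsvm_pred=rs_p,
            )
            flags[key] = {
                "gene": gene,
                "deleterious": deleterious,
                "rare": not contaminant,
                "in_panel": False,
            }
            gene_keys.append(key)

        # carrier draws: one Bernoulli per sample at the arm's carrier prob,
        # carriers assigned one of the gene's variants (het)
        p_case, p_ctrl = planted.get(
            gene, (cfg.background_carrier_prob, cfg.background_carrier_prob)
        )
        probs = np.where(case_mask, p_case, p_ctrl)
        carrier = rng.random(n_samples) < probs
        gene_cols = {k: np.zeros(n_samples, dtype=np.int8) for k in gene_keys}
        for si in np.flatnonzero(carrier):
            chosen = gene_keys[int(rng.integers(len(gene_keys)))]
            gene_cols[chosen][si] = 1
        realized[gene] = (
            int((carrier & case_mask).sum()),
            int((carrier & ~case_mask).sum()),
        )
        for k in gene_keys:
            keys.append(k)
            columns.append(gene_cols[k])

    carriage = np.stack(columns, axis=1)
    cohort = CohortGenotypes(samples, phenotype, keys, carriage)

    # panel: configured fraction of variants observed in >= 1 control
    ctrl_rows = ~case_mask
    observed_in_controls = [
        k for j, k in enumerate(keys) if (carriage[ctrl_rows, j] > 0).any()
    ]
    panel: set[VariantKey] = set()
    for k in observed_in_controls:
        if rng.random() < cfg.panel_overlap_frac:
            panel.add(k)
            flags[k]["in_panel"] = True

    truth = SimTruth(
        planted_genes=list(cfg.planted_genes),
        realized_carriers=realized,
        variant_flags=flags,
    )
    return cohort, annotations, panel, truth


def _write_vcf(cohort: CohortGenotypes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrS>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        order = np.lexsort(
            (
                [k.alt for k in cohort.variants],
                [k.ref for k in cohort.variants],
                [k.pos for k in cohort.variants],
            )
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j in order:
            k = cohort.variants[j]
            gts = "\t".join(gt_map[int(v)] for v in cohort.carriage[:, j])
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _fmt(v) -> str:
    return "." if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v))


def _write_annotations(annotations, path: str) -> None:
    cols = [
        "CHROM", "POS", "REF", "ALT", "GENE", "CONSEQUENCE",
        "AF_1000G_EAS", "AF_EXAC_EAS", "MT_SCORE", "MT_PRED",
        "RSVM_SCORE", "RSVM_PRED", "PROTEIN_CHANGE",
    ]
    keys = sorted(annotations)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for k in keys:
            v = annotations[k]
            fh.write(
                "\t".join(
                    [
                        k.chrom, str(k.pos), k.ref, k.alt, v.gene, v.consequence,
                        _fmt(v.af_1000g), _fmt(v.af_exac), _fmt(v.mt_score),
                        _fmt(v.mt_pred), _fmt(v.rsvm_score), _fmt(v.rsvm_pred),
                        _fmt(v.protein_change),
                    ]
                )
                + "\n"
            )


def simulate_cohort(cfg: SimConfig, out_dir: str) -> SimTruth:
    """Generate and write the cohort fixture files into ``out_dir``.

    Emits cohort.vcf, annotations.tsv, panel.tsv, phenotypes.tsv and
    truth.tsv (per-gene realized carrier counts).  Deterministic per seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    cohort, annotations, panel, truth = simulate_cohort_data(cfg)
    _write_vcf(cohort, os.path.join(out_dir, "cohort.vcf"))
    _write_annotations(annotations, os.path.join(out_dir, "annotations.tsv"))
    with open(os.path.join(out_dir, "panel.tsv"), "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\n")
        for k in sorted(panel):
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")
    with open(os.path.join(out_dir, "phenotypes.tsv"), "w") as fh:
        fh.write("SAMPLE\tPHENOTYPE\n")
        for s in cohort.samples:
            fh.write(f"{s}\t{cohort.phenotype[s]}\n")
    pd.DataFrame(
        {
            "GENE": sorted(truth.realized_carriers),
            "CASE_CARRIERS": [
                truth.realized_carriers[g][0] for g in sorted(truth.realized_carriers)
            ],
            "CONTROL_CARRIERS": [
                truth.realized_carriers[g][1] for g in sorted(truth.realized_carriers)
            ],
        }
    ).to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# Gene sets


def simulate_gene_sets(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GeneSetCollection, str | None]:
    """Flat gene-set terms over the gene universe, plus the planted term id.

    Term sizes follow a lognormal with median 20 clipped to [5, 200]; the
    planted term (when configured) has a fixed, representative size of a
    large functional class (default 40 genes) so that planting acts on the
    odds of membership in the mutated list, not on term size.
    """
    if cfg.n_terms < 1:
        raise InputError("n_terms must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    genes = np.array(cfg.gene_names())
    # odds of 1 means no planting: the term is then drawn like any other
    planted_id = (
        cfg.planted_term[0]
        if cfg.planted_term and cfg.planted_term[1] != 1.0
        else None
    )
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for ti in range(cfg.n_terms):
        term_id = f"TERM{ti + 1:04d}"
        if term_id == planted_id:
            size = min(cfg.planted_term_size, cfg.n_genes)
        else:
            size = int(np.clip(rng.lognormal(np.log(20.0), 0.6), 5, 200))
            size = min(size, cfg.n_genes)
        members = rng.choice(genes, size=size, replace=False)
        terms[term_id] = (f"synthetic process {ti + 1}", frozenset(members.tolist()))
    collection = GeneSetCollection(terms=terms, background=frozenset(genes.tolist()))
    return collection, planted_id if planted_id in terms else None


def simulate_mutated_genes(
    collection: GeneSetCollection,
    planted_term: str | None,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw a mutated-gene list with the planted term's genes over-sampled.

    Background genes enter with probability ``list_baseline_prob``; genes
    of the planted term enter with the probability whose odds are
    ``enrichment_odds`` times the baseline odds.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    p0 = cfg.list_baseline_prob
    odds = cfg.planted_term[1] if cfg.planted_term else 1.0
    odds1 = odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    planted_members = (
        collection.terms[planted_term][1] if planted_term else frozenset()
    )
    chosen = []
    for gene in sorted(collection.background):
        p = p1 if gene in planted_members else p0
        if rng.random() < p:
            chosen.append(gene)
    return chosen


def write_gene_sets(collection: GeneSetCollection, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "gene_sets.tsv"), "w") as fh:
        fh.write("TERM_ID\tTERM_NAME\tGENES\n")
        for term_id in sorted(collection.terms):
            name, genes = collection.terms[term_id]
            fh.write(f"{term_id}\t{name}\t{','.join(sorted(genes))}\n")
    with open(os.path.join(out_dir, "background.txt"), "w") as fh:
        for g in sorted(collection.background):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Edges


def simulate_edges(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> InteractionEdgeList:
    """Directed Erdos-Renyi edges over the gene universe (no self-loops)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    genes = cfg.gene_names()
    n = len(genes)
    if cfg.edge_density <= 0 or n < 2:
        return InteractionEdgeList(edges=[])
    mask = rng.random((n, n)) < cfg.edge_density
    np.fill_diagonal(mask, False)
    src_idx, dst_idx = np.nonzero(mask)
    edges = [
        (genes[i], genes[j], "interaction") for i, j in zip(src_idx, dst_idx)
    ]
    return InteractionEdgeList(edges=edges)


def write_edges(edges: InteractionEdgeList, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("SOURCE\tTARGET\tRELATION\n")
        for s, t, r in sorted(edges.edges):
            fh.write(f"{s}\t{t}\t{r}\n")


# ---------------------------------------------------------------------------
# Carrier-level null draws (calibration testing)


def simulate_null_tables(
    n_genes: int,
    n_cases: int,
    n_controls: int,
    carrier_prob: float,
    rng: np.random.Generator,
):
    """Per-gene 2x2 carrier counts under the null: the same carrier
    probability in both arms, independent across genes and samples."""
    a = rng.binomial(n_cases, carrier_prob, size=n_genes)
    c = rng.binomial(n_controls, carrier_prob, size=n_genes)
    return a, c
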