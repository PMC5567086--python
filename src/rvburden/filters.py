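"""Qualifying-variant filter cascade.

Four per-variant predicates applied in a fixed reporting order:

1. consequence class inclusion (nonsense, splice-site, missense, indel),
2. rarity (every available reference-population MAF strictly below the
   threshold; a variant absent from the reference panels passes),
3. in-house panel exclusion (exact chrom/pos/ref/alt match),
4. dual-predictor deleteriousness concordance (both MutationTaster and
   RadialSVM call the variant damaging).

Each predicate is pure and per-variant, so the surviving set is
order-invariant; only the per-stage counts in the trace depend on order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import AnnotatedVariant, InputError, VariantKey

logger = logging.getLogger("rvburden")

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "passes_consequence",
    "passes_rarity",
    "passes_predictors",
    "exclude_panel",
    "apply_cascade",
]

DEFAULT_CONSEQUENCES = frozenset(
    {"nonsense", "splice_site", "missense", "frameshift_indel", "inframe_indel"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the cascade.

    maf_threshold
        Strict upper bound on every available population MAF (default 0.01,
        i.e. "rare" = MAF < 1%).
    included_consequences
        Consequence classes retained (default: the nonsynonymous and
        splicing classes; synonymous and other are dropped).
    require_both_predictors
        When true (default) both predictor calls must be "D".
    missing_af_passes
        A variant with no reference-population frequency ("novel") passes
        rarity (default true).
    missing_pred_policy
        "fail": a missing predictor call fails the predictor stage;
        "pass_if_other_D": a missing call is forgiven when the other
        predictor calls "D" (useful for indels that some predictors skip).
    """

    maf_threshold: float = 0.01
    included_consequences: frozenset[str] = DEFAULT_CONSEQUENCES
    require_both_predictors: bool = True
    missing_af_passes: bool = True
    missing_pred_policy: str = "fail"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise InputError(f"maf_threshold must be in (0,1], got {self.maf_threshold}")
        if not self.included_consequences:
            raise InputError("included_consequences must be non-empty")
        if self.missing_pred_policy not in ("fail", "pass_if_other_D"):
            raise InputError(f"unknown missing_pred_policy {self.missing_pred_policy!r}")

    def as_dict(self) -> dict:
        return {
            "maf_threshold": self.maf_threshold,
            "included_consequences": ",".join(sorted(self.included_consequences)),
            "require_both_predictors": self.require_both_predictors,
            "missing_af_passes": self.missing_af_passes,
            "missing_pred_policy": self.missing_pred_policy,
        }


@dataclass
class FilterTrace:
    """Flowchart-style record: variants surviving after each stage."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, n: int) -> None:
        if self.stages and n > self.stages[-1][1]:
            raise ValueError("filter trace counts must be non-increasing")
        self.stages.append((name, n))

    def counts(self) -> dict[str, int]:
        return dict(self.stages)


def passes_consequence(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff the variant's consequence class is retained."""
    return v.consequence in cfg.included_consequences


def passes_rarity(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff every available population frequency is < maf_threshold.

    Frequencies are folded to minor-allele frequency before comparison, so
    a reported alternate-allele frequency of 0.995 is as rare as 0.005.
    """
    freqs = [f for f in (v.af_1000g, v.af_exac) if f is not None]
    if not freqs:
        return cfg.missing_af_passes
    return all(min(f, 1.0 - f) < cfg.maf_threshold for f in freqs)


def passes_predictors(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff the deleteriousness predictors concur on "damaging"."""
    if not cfg.require_both_predictors:
        return v.mt_pred == "D" or v.rsvm_pred == "D"
    mt, rsvm = v.mt_pred, v.rsvm_pred
    if mt is not None and rsvm is not None:
        return mt == "D" and rsvm == "D"
    if cfg.missing_pred_policy == "fail":
        return False
    # pass_if_other_D: the available call must be "D"
    present = mt if mt is not None else rsvm
    return present == "D"


def exclude_panel(
    variants: list[AnnotatedVariant], panel: set[VariantKey]
) -> list[AnnotatedVariant]:
    """Drop variants whose key appears in the in-house panel (exact match)."""
    return [v for v in variants if v.key not in panel]


def apply_cascade(
    variant_keys: list[VariantKey],
    annotations: dict[VariantKey, AnnotatedVariant],
    panel: set[VariantKey],
    cfg: FilterConfig | None = None,
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Run the full cascade over the cohort's variants.

    Returns the qualifying variants (annotation records, input order
    preserved) and a FilterTrace with survivors after each stage in the
    order consequence -> rarity -> panel exclusion -> predictors.
    Unannotated variants are dropped up front; more than 10% unannotated
    signals a genotype/annotation mismatch and raises.
    """
    cfg = cfg or FilterConfig()
    trace = FilterTrace()
    trace.add("input", len(variant_keys))

    annotated = [annotations[k] for k in variant_keys if k in annotations]
    n_missing = len(variant_keys) - len(annotated)
    if variant_keys and n_missing / len(variant_keys) > 0.10:
        raise InputError(
            f"{n_missing}/{len(variant_keys)} cohort variants lack annotation "
            "rows; genotype and annotation inputs appear mismatched"
        )
    if n_missing:
        logger.warning("dropping %d unannotated variant(s)", n_missing)
    trace.add("annotated", len(annotated))

    surviving = [v for v in annotated if passes_consequence(v, cfg)]
    trace.add("consequence", len(surviving))
    surviving = [v for v in surviving if passes_rarity(v, cfg)]
    trace.add("rarity", len(surviving))
    surviving = exclude_panel(surviving, panel)
    trace.add("panel_exclusion", len(surviving))
    surviving = [v for v in surviving if passes_predictors(v, cfg)]
    trace.add("predictors", len(surviving))
    return surviving, trace
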