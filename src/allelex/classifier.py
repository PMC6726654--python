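"""Expression-group classification of mutations.

Each mutation is placed into exactly one group from its total read
count ``t = wt + mut`` and RNA mutant-allele frequency:

* ``N_EX`` — neither allele expressed: ``t`` below the discard band
  (default: fewer than 3 reads, including zero coverage);
* ``DISCARDED`` — ``t`` inside the unreliable band [3, 9], where
  misalignments or shallow coverage could flip the call;
* ``V_EX`` — variant allele expressed: ``t`` above the band and
  RNA MAF at or above 2.5%;
* ``W_EX`` — only the wild-type allele expressed: ``t`` above the band
  and RNA MAF below 2.5%.

The band bounds are inclusive on both ends and apply to the possibly
fractional totals produced by indel depth averaging; the MAF threshold
is inclusive on the V-ex side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import math

import pandas as pd

from .allele_counter import AlleleCounts
from .errors import CompletenessError
from .genome_builder import MutationRecord

GROUPS = ("V_EX", "W_EX", "N_EX", "DISCARDED")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the group assignment.

    ``discard_min``/``discard_max`` bound the discard band in total
    reads; totals strictly below ``discard_min`` are N-ex.
    ``vex_min_maf`` is the RNA MAF separating V-ex from W-ex.
    """

    discard_min: float = 3.0
    discard_max: float = 9.0
    vex_min_maf: float = 0.025

    def __post_init__(self) -> None:
        if not 0 <= self.discard_min <= self.discard_max:
            raise ValueError("need 0 <= discard_min <= discard_max")
        if not 0 < self.vex_min_maf < 1:
            raise ValueError("vex_min_maf must be in (0, 1)")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class ExpressionCall:
    group: str
    counts: AlleleCounts
    config: ClassifierConfig


def classify(counts: AlleleCounts, config: ClassifierConfig = DEFAULT_CONFIG) -> ExpressionCall:
    """Assign the expression group for one mutation's allele counts."""
    total = counts.total
    if total < config.discard_min:
        group = "N_EX"
    elif total <= config.discard_max:
        group = "DISCARDED"
    elif counts.rna_maf >= config.vex_min_maf:
        group = "V_EX"
    else:
        group = "W_EX"
    return ExpressionCall(group=group, counts=counts, config=config)


PROFILE_COLUMNS = (
    "sample", "gene", "chrom", "pos", "ref", "alt", "type", "dna_af",
    "wt_reads", "mut_reads", "total", "rna_maf", "group",
)


def build_profile(
    sample_id: str,
    mutations: Sequence[MutationRecord],
    counts: Union[pd.DataFrame, Mapping],
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Join mutations with their allele counts into an expression profile.

    ``counts`` is the table from :func:`allelex.allele_counter.count_sample`
    (keyed by base gene symbol and genomic position) or a mapping
    ``(gene, pos) -> AlleleCounts``.  Every mutation must be covered;
    rows come back in deterministic (gene, pos) order with DNA and RNA
    allele frequencies side by side.
    """
    if isinstance(counts, pd.DataFrame):
        lookup = {}
        for _, row in counts.iterrows():
            key = (str(row["gene"]).split("#", 1)[0], int(row["genomic_pos"]))
            lookup[key] = AlleleCounts(float(row["wt_reads"]), float(row["mut_reads"]))
    else:
        lookup = dict(counts)

    rows = []
    for m in sorted(mutations, key=lambda m: (m.gene, m.pos)):
        key = (m.gene, m.pos)
        if key not in lookup:
            raise CompletenessError(f"no allele counts for mutation {m.gene}:{m.pos}")
        ac = lookup[key]
        call = classify(ac, config)
        maf = ac.rna_maf
        rows.append({
            "sample": sample_id, "gene": m.gene, "chrom": m.chrom, "pos": m.pos,
            "ref": m.ref, "alt": m.alt, "type": m.mtype,
            "dna_af": math.nan if m.dna_af is None else m.dna_af,
            "wt_reads": ac.wt_reads, "mut_reads": ac.mut_reads, "total": ac.total,
            "rna_maf": math.nan if maf is None else maf,
            "group": call.group,
        })
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def summarize_groups(profiles: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Per-sample and pooled group counts and fractions.

    Fractions are over *classified* (non-discarded) mutations and sum to
    one per sample; pooled counts are the plain sums over samples.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []

    def one(sample: str, frame: pd.DataFrame) -> dict:
        n = {g: int((frame["group"] == g).sum()) for g in GROUPS}
        classified = n["V_EX"] + n["W_EX"] + n["N_EX"]
        row = {"sample": sample, "n_mutations": len(frame), "n_discarded": n["DISCARDED"]}
        for g in ("V_EX", "W_EX", "N_EX"):
            row[f"n_{g.lower()}"] = n[g]
            row[f"frac_{g.lower()}"] = n[g] / classified if classified else math.nan
        return row

    for frame in profiles:
        sample = str(frame["sample"].iloc[0]) if len(frame) else ""
        rows.append(one(sample, frame))
    pooled = pd.concat(profiles, ignore_index=True) if len(profiles) > 1 else profiles[0]
    rows.append(one("POOLED", pooled))
    return pd.DataFrame(rows)


def write_profile(profile: pd.DataFrame, path: Union[str, Path]) -> None:
    profile.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profile(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample": str, "gene": str, "chrom": str})
    return frame[list(PROFILE_COLUMNS)]
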