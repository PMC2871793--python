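"""Haplodiploid sexing from microsatellite genotypes.

In Hymenoptera females develop from fertilized (diploid) eggs and males
from unfertilized (haploid) eggs, so a specimen heterozygous at any
microsatellite locus is provably diploid and female, while a specimen
with a single allele at every amplified locus is *potentially* male
(a diploid homozygous at all loci looks identical; with six moderately
polymorphic loci that is rare). Three alleles at any locus indicate a
triploid, and a specimen where nothing amplified cannot be scored.

The minimum number of heterozygous loci required to call a female is
configurable: 1 (one heterozygous locus already proves diploidy) or 2
(the stricter variant); both conventions appear in the source
literature and are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .errors import MalformedRecordError
from .simulate import GenotypeTable

__all__ = ["GenotypeRecord", "PloidyCall", "classify_ploidy", "filter_females"]


@dataclass
class GenotypeRecord:
    """One specimen's allele calls, in a fixed locus order.

    Each locus is a collection of distinct allele labels: empty = failed
    amplification, 1-3 labels otherwise.
    """

    specimen_id: str
    loci: Sequence[Sequence]
    collection_year: int | None = None
    rearing: Literal["foundress_reared", "worker_reared"] | None = None


@dataclass
class PloidyCall:
    specimen_id: str
    call: Literal["female_diploid", "potential_male", "triploid", "unscored"]
    n_heterozygous_loci: int
    n_amplified_loci: int


def classify_ploidy(rec: GenotypeRecord, min_het_loci: int = 1) -> PloidyCall:
    """Classify one specimen.

    Rules, in order: any locus with 3 distinct alleles -> triploid; no
    amplified locus -> unscored; at least ``min_het_loci`` heterozygous
    (2-allele) loci -> female_diploid; otherwise potential_male. Failed
    loci are simply excluded from counting.
    """
    n_het = 0
    n_amp = 0
    any_triploid = False
    for i, alleles in enumerate(rec.loci):
        distinct = set(alleles)
        if len(distinct) > 3:
            raise MalformedRecordError(
                f"specimen {rec.specimen_id!r}: locus {i + 1} has "
                f"{len(distinct)} alleles (max 3)"
            )
        if not distinct:
            continue
        n_amp += 1
        if len(distinct) == 3:
            any_triploid = True
        elif len(distinct) == 2:
            n_het += 1
    if any_triploid:
        call = "triploid"
    elif n_amp == 0:
        call = "unscored"
    elif n_het >= min_het_loci:
        call = "female_diploid"
    else:
        call = "potential_male"
    return PloidyCall(
        specimen_id=rec.specimen_id,
        call=call,
        n_heterozygous_loci=n_het,
        n_amplified_loci=n_amp,
    )


def filter_females(
    table: GenotypeTable, min_het_loci: int = 1
) -> tuple[list[str], pd.DataFrame]:
    """Keep specimens called female_diploid; log everyone removed.

    Returns ``(female ids, exclusion log)`` where the log has one row
    per excluded specimen with columns ``specimen_id, call, reason``.
    Every input specimen lands in exactly one of the two outputs.
    """
    if len(table.genotypes) == 0:
        raise MalformedRecordError("genotype table is empty")
    females: list[str] = []
    excluded: list[dict] = []
    for sp in table.specimens:
        rec = GenotypeRecord(
            specimen_id=str(sp), loci=list(table.genotypes.loc[sp])
        )
        result = classify_ploidy(rec, min_het_loci=min_het_loci)
        if result.call == "female_diploid":
            females.append(str(sp))
        else:
            reasons = {
                "potential_male": "single allele at every amplified locus",
                "triploid": "three alleles at one or more loci",
                "unscored": "no microsatellites amplified",
            }
            excluded.append(
                {
                    "specimen_id": str(sp),
                    "call": result.call,
                    "reason": reasons[result.call],
                }
            )
    log = pd.DataFrame(excluded, columns=["specimen_id", "call", "reason"])
    return females, log
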