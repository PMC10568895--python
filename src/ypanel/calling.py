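"""Depth-thresholded allele calling and profile comparison.

Per-locus read counts become ancestral/derived calls under two depth
cutoffs: a *detection* threshold (below it the genotype is filtered out)
and an *analysis* threshold (between the two the call is kept but marked
for review).  Loci are hemizygous: exactly two legitimate alleles; reads
matching neither count toward depth but never toward a call, and an
excess of them (or a weak majority) flags the locus as mixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import Marker

logger = logging.getLogger(__name__)

#: Fraction of the panel below which a profile is reported as carrying
#: no reliable male DNA (female / negative-control pattern).
NO_MALE_DNA_FRACTION = 0.05

#: Maximum tolerated fraction of reads matching neither legitimate allele.
OTHER_READS_MAX_FRACTION = 0.1


class CallState(str, Enum):
    ANCESTRAL = "ANCESTRAL"
    DERIVED = "DERIVED"
    NO_CALL = "NO_CALL"


class CallStatus(str, Enum):
    PASS = "PASS"
    REVIEW = "REVIEW"
    FILTERED = "FILTERED"
    MIXED_FLAG = "MIXED_FLAG"


@dataclass(frozen=True)
class CallingThresholds:
    """Read-depth cutoffs for genotype calling.

    ``detection``/``analysis`` default to the validated 18/54 reads.
    ``allele_fraction_min`` is the majority fraction (among the two
    legitimate alleles) below which a call is flagged as mixed.
    """

    detection: int = 18
    analysis: int = 54
    allele_fraction_min: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.detection <= self.analysis):
            raise ValueError(
                f"need 0 < detection <= analysis, got {self.detection}/{self.analysis}"
            )
        if not (0.5 < self.allele_fraction_min <= 1.0):
            raise ValueError("allele_fraction_min must be in (0.5, 1]")


@dataclass(frozen=True)
class LocusReadCount:
    """Read tally at one locus: ancestral + derived + other = depth."""

    marker_name: str
    depth: int
    ancestral_reads: int
    derived_reads: int
    other_reads: int = 0

    def __post_init__(self) -> None:
        for fld in ("depth", "ancestral_reads", "derived_reads", "other_reads"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{self.marker_name}: negative {fld}")
        if self.ancestral_reads + self.derived_reads + self.other_reads != self.depth:
            raise ValueError(
                f"{self.marker_name}: allele reads do not sum to depth "
                f"({self.ancestral_reads}+{self.derived_reads}+{self.other_reads}"
                f" != {self.depth})"
            )


@dataclass(frozen=True)
class GenotypeCall:
    """Call at one locus.  ``depth`` is None for calls whose source does
    not measure read depth (e.g. genotypes lifted from a VCF)."""

    marker_name: str
    state: CallState
    status: CallStatus
    depth: int | None
    major_allele_fraction: float | None = None

    @property
    def is_called(self) -> bool:
        return self.state is not CallState.NO_CALL


def _filtered_call(marker_name: str, depth: int | None = 0) -> GenotypeCall:
    return GenotypeCall(marker_name, CallState.NO_CALL, CallStatus.FILTERED, depth, None)


def call_locus(counts: LocusReadCount, thresholds: CallingThresholds | None = None) -> GenotypeCall:
    """Call one locus from its read tally.

    Below detection: filtered (no call).  Otherwise the majority of the
    two legitimate alleles gives the state; status is REVIEW inside the
    detection..analysis window and PASS above, overridden by MIXED_FLAG
    when the majority fraction is below ``allele_fraction_min`` or when
    off-target reads exceed their tolerated share.
    """
    thresholds = thresholds or CallingThresholds()
    if counts.depth < thresholds.detection:
        return _filtered_call(counts.marker_name, counts.depth)
    informative = counts.ancestral_reads + counts.derived_reads
    if informative == 0:
        # depth is all off-target reads; keep the locus visible as mixed
        return GenotypeCall(
            counts.marker_name, CallState.ANCESTRAL, CallStatus.MIXED_FLAG, counts.depth, 0.0
        )
    if counts.derived_reads > counts.ancestral_reads:
        state = CallState.DERIVED
    else:
        state = CallState.ANCESTRAL  # ties resolve conservatively to ancestral
    fraction = max(counts.ancestral_reads, counts.derived_reads) / informative
    status = (
        CallStatus.REVIEW if counts.depth < thresholds.analysis else CallStatus.PASS
    )
    if fraction < thresholds.allele_fraction_min:
        status = CallStatus.MIXED_FLAG
    elif counts.other_reads / counts.depth > OTHER_READS_MAX_FRACTION:
        status = CallStatus.MIXED_FLAG
    return GenotypeCall(counts.marker_name, state, status, counts.depth, fraction)


@dataclass
class SampleProfile:
    """Per-sample calls, one per panel marker."""

    sample_id: str
    calls: dict[str, GenotypeCall]
    flagged: tuple[str, ...] = ()  # loci excluded for allele mismatches (VCF path)

    @property
    def called_count(self) -> int:
        return sum(1 for c in self.calls.values() if c.is_called)

    @property
    def mean_depth(self) -> float:
        depths = [c.depth for c in self.calls.values() if c.depth is not None]
        return float(sum(depths) / len(depths)) if depths else math.nan

    def states(self) -> dict[str, CallState]:
        return {name: c.state for name, c in self.calls.items()}

    def no_reliable_male_dna(self, fraction: float = NO_MALE_DNA_FRACTION) -> bool:
        """Female/negative pattern: fewer than ``fraction`` of loci called."""
        return self.called_count < fraction * len(self.calls)


def call_sample(
    counts: Iterable[LocusReadCount],
    panel: Sequence[Marker],
    thresholds: CallingThresholds | None = None,
    sample_id: str = "sample",
) -> SampleProfile:
    """Call every panel locus for one sample.

    Loci absent from ``counts`` become filtered no-calls at depth 0;
    counts for markers outside the panel raise.
    """
    thresholds = thresholds or CallingThresholds()
    panel_names = {m.name for m in panel}
    calls: dict[str, GenotypeCall] = {}
    for c in counts:
        if c.marker_name not in panel_names:
            raise KeyError(f"unknown marker {c.marker_name!r} in read counts")
        if c.marker_name in calls:
            raise ValueError(f"duplicate read counts for marker {c.marker_name!r}")
        calls[c.marker_name] = call_locus(c, thresholds)
    ordered = {
        m.name: calls.get(m.name, _filtered_call(m.name)) for m in panel
    }
    return SampleProfile(sample_id=sample_id, calls=ordered)


@dataclass
class ConcordanceReport:
    """Pairwise profile comparison over a shared panel."""

    co_called: tuple[str, ...]
    discordant: tuple[str, ...]
    dropped_in_a_only: tuple[str, ...]
    dropped_in_b_only: tuple[str, ...]

    @property
    def concordance(self) -> float:
        """Fraction of co-called loci with identical states (NaN if none)."""
        if not self.co_called:
            return math.nan
        return 1.0 - len(self.discordant) / len(self.co_called)


def compare_profiles(a: SampleProfile, b: SampleProfile) -> ConcordanceReport:
    if set(a.calls) != set(b.calls):
        raise ValueError("profiles cover different panels")
    co, disc, only_a, only_b = [], [], [], []
    for name, ca in a.calls.items():
        cb = b.calls[name]
        if ca.is_called and cb.is_called:
            co.append(name)
            if ca.state is not cb.state:
                disc.append(name)
        elif cb.is_called:  # dropped in a only
            only_a.append(name)
        elif ca.is_called:  # dropped in b only
            only_b.append(name)
    return ConcordanceReport(tuple(co), tuple(disc), tuple(only_a), tuple(only_b))


@dataclass
class CoverageReport:
    """Depth-of-coverage statistics over a set of profiles."""

    per_locus_mean: dict[str, float]
    per_sample_mean: dict[str, float]
    overall_mean: float
    lowest_locus: tuple[str, float]
    highest_locus: tuple[str, float]


def coverage_metrics(profiles: Sequence[SampleProfile]) -> CoverageReport:
    """Per-locus and per-sample mean depths; loci ranked by mean DOC.

    Calls without a measured depth (VCF-derived) are excluded.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    records = [
        (p.sample_id, name, c.depth)
        for p in profiles
        for name, c in p.calls.items()
        if c.depth is not None
    ]
    if not records:
        raise ValueError("no measured depths in the given profiles")
    df = pd.DataFrame(records, columns=["sample", "marker", "depth"])
    per_locus = df.groupby("marker")["depth"].mean()
    per_sample = df.groupby("sample")["depth"].mean()
    return CoverageReport(
        per_locus_mean=per_locus.to_dict(),
        per_sample_mean=per_sample.to_dict(),
        overall_mean=float(df["depth"].mean()),
        lowest_locus=(per_locus.idxmin(), float(per_locus.min())),
        highest_locus=(per_locus.idxmax(), float(per_locus.max())),
    )


def read_counts_tsv(path: str | Path) -> dict[str, list[LocusReadCount]]:
    """Read a per-sample per-locus read-count table
    (``sample  marker  depth  ancestral_reads  derived_reads  other_reads``)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "marker", "depth", "ancestral_reads", "derived_reads", "other_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"read-count file {path}: missing columns {missing}")
    out: dict[str, list[LocusReadCount]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            LocusReadCount(
                marker_name=str(row.marker),
                depth=int(row.depth),
                ancestral_reads=int(row.ancestral_reads),
                derived_reads=int(row.derived_reads),
                other_reads=int(row.other_reads),
            )
        )
    return out


def counts_to_table(counts_by_sample: Mapping[str, Sequence[LocusReadCount]]) -> pd.DataFrame:
    rows = [
        (s, c.marker_name, c.depth, c.ancestral_reads, c.derived_reads, c.other_reads)
        for s, counts in counts_by_sample.items()
        for c in counts
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "marker", "depth", "ancestral_reads", "derived_reads", "other_reads"],
    )


def extract_panel_genotypes_from_vcf(
    vcf_path: str | Path,
    panel: Sequence[Marker],
    sample: str | None = None,
) -> SampleProfile:
    """Lift panel genotypes out of a GRCh38 chrY VCF.

    The ancestral/derived orientation is resolved against the panel's
    alleles, not REF/ALT order.  Panel positions absent from the VCF are
    no-calls; records whose alleles match neither panel allele are
    flagged and excluded (listed in ``profile.flagged``).  Depth is taken
    from FORMAT/DP when present, else left unmeasured.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    vcf_samples = list(vf.header.samples)
    if not vcf_samples:
        raise ValueError(f"{vcf_path}: sites-only VCF, no genotypes to extract")
    if sample is None:
        sample = vcf_samples[0]
    elif sample not in vcf_samples:
        raise KeyError(f"sample {sample!r} not in VCF (has {vcf_samples})")

    by_pos: dict[int, list[Marker]] = {}
    for m in panel:
        by_pos.setdefault(m.position, []).append(m)

    calls: dict[str, GenotypeCall] = {m.name: _filtered_call(m.name, depth=None) for m in panel}
    flagged: list[str] = []
    for rec in vf:
        contig = rec.contig
        if contig == "Y":
            logger.debug("normalising contig 'Y' to 'chrY'")
            contig = "chrY"
        if contig != "chrY" or rec.pos not in by_pos:
            continue
        fmt = rec.samples[sample]
        gt = fmt.get("GT")
        depth = fmt.get("DP") if "DP" in fmt else None
        for marker in by_pos[rec.pos]:
            alleles = set(rec.alleles or ())
            if not alleles & {marker.ancestral_allele, marker.derived_allele}:
                logger.warning(
                    "marker %s at %d: VCF alleles %s match neither panel allele; excluded",
                    marker.name, rec.pos, sorted(alleles),
                )
                flagged.append(marker.name)
                continue
            idx = next((i for i in (gt or ()) if i is not None), None)
            if idx is None:
                continue  # missing genotype stays a no-call
            observed = rec.alleles[idx]
            if observed == marker.derived_allele:
                state = CallState.DERIVED
            elif observed == marker.ancestral_allele:
                state = CallState.ANCESTRAL
            else:
                logger.warning(
                    "marker %s: carried allele %r matches neither panel allele; excluded",
                    marker.name, observed,
                )
                flagged.append(marker.name)
                continue
            calls[marker.name] = GenotypeCall(
                marker.name, state, CallStatus.PASS,
                int(depth) if depth is not None else None, None,
            )
    return SampleProfile(sample_id=sample, calls=calls, flagged=tuple(sorted(set(flagged))))
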