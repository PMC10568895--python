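"""Synthetic fixtures: panels, tree-consistent genotypes, pedigrees and
read counts under the developmental-validation scenarios.

Every generator is deterministic under its seed and ships the ground
truth alongside its output, so calling, inference and population
statistics can be tested closed-loop without any external data.  The
unit of simulation is the per-locus read count (the calling module's
input); no read-level data is generated.

Scenario models (dilution, male-female mixture, PCR inhibition,
ultrasonic degradation, female-only negative controls) reproduce the
*shape* of the corresponding bench experiments — depth falls with input
mass, long amplicons drop out first on fragmented DNA, stray female
reads never carry the male's derived alleles — with defaults calibrated
once against the published validation yields (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallingThresholds, LocusReadCount, counts_to_table
from .panel import (
    HaplogroupTree,
    Marker,
    MarkerClass,
    build_tree,
    markers_to_table,
    parse_haplogroup_name,
    write_panel,
)
from .popstats import PedigreeGraph

_BASES = ("A", "C", "G", "T")

#: Default clade mix of generated panels; C+D+N+O+Q+R dominate, echoing
#: the geometry of large Chinese-population panels.
DEFAULT_CLADE_MIX: dict[str, float] = {
    "O": 0.58, "C": 0.11, "N": 0.08, "Q": 0.06,
    "D": 0.05, "R": 0.05, "J": 0.04, "G": 0.03,
}

#: Depth retention per (inhibitor, dose) pair: a dose-response table in
#: the units of the bench gradients (ng/uL for tannic and humic acid,
#: uM for hematin), shaped like the published inhibition curves —
#: near-full retention below the tolerated dose, then a steep collapse.
INHIBITOR_RETENTION: dict[str, dict[float, float]] = {
    "tannic_acid": {25: 1.0, 50: 1.0, 100: 0.012, 150: 0.004, 200: 0.002, 250: 0.001, 300: 0.001},
    "humic_acid": {15: 1.0, 20: 1.0, 25: 0.012, 30: 0.004, 35: 0.002, 40: 0.001, 45: 0.001},
    "hematin": {12.5: 1.0, 25: 1.0, 37.5: 1.0, 50: 0.004, 62.5: 0.002, 75: 0.001, 87.5: 0.001},
}


# ---------------------------------------------------------------------------
# Depth model and scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthModel:
    """Overdispersed per-locus sequencing-depth model.

    Depth at locus l is negative-binomial with mean
    ``baseline_mean_depth * mass_scale * effect_l * survival_l`` and
    variance ``mu + dispersion * mu^2``.  ``effect_l`` is a fixed
    locus-intrinsic amplification efficiency, lognormal with unit mean
    and spread ``locus_sigma`` — fixed because amplification efficiency
    is a property of the locus, reproducible across runs.  Defaults give
    a 1 ng library a mean depth of coverage around 3,741x.
    """

    baseline_mean_depth: float = 3741.0
    locus_sigma: float = 0.5
    dispersion: float = 0.3
    mass_scale: float = 1.0
    effect_seed: int = 7

    def __post_init__(self) -> None:
        if self.baseline_mean_depth <= 0 or self.dispersion <= 0 or self.mass_scale <= 0:
            raise ValueError("depth-model parameters must be positive")
        if self.locus_sigma < 0:
            raise ValueError("locus_sigma must be >= 0")

    def locus_effects(self, marker_names: Sequence[str]) -> dict[str, float]:
        """Deterministic unit-mean lognormal efficiency per locus."""
        rng = np.random.default_rng(self.effect_seed)
        s = self.locus_sigma
        draws = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=len(marker_names))
        return dict(zip(marker_names, draws))


@dataclass(frozen=True)
class DilutionScenario:
    """Serial-dilution sensitivity run: input mass relative to 1 ng."""

    mass_ng: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_ng < 0:
            raise ValueError("mass must be >= 0")


@dataclass(frozen=True)
class DegradationScenario:
    """Ultrasonic-degradation run summarised by its degradation index.

    Amplicon survival decays with length: survival = exp(-len / L) with
    L = length_scale / ln(DI); DI <= 1 means no degradation (survival 1).
    The published yields give no mechanistic model, only (DI, loci
    called) anchors, so the form is chosen for monotonicity in both
    length and DI and ``length_scale`` is calibrated, not asserted.
    """

    di: float
    length_scale: float = 110.0

    def __post_init__(self) -> None:
        if self.di < 1:
            raise ValueError(f"degradation index must be >= 1, got {self.di}")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")

    def survival(self, amplicon_length: int) -> float:
        if self.di <= 1.0:
            return 1.0
        return math.exp(-amplicon_length * math.log(self.di) / self.length_scale)

    @classmethod
    def calibrated(
        cls,
        panel: Sequence[Marker],
        depth_model: DepthModel,
        di: float = 11.76,
        target_called: float = 529.0,
        thresholds: CallingThresholds | None = None,
    ) -> "DegradationScenario":
        """Choose length_scale so the expected number of called loci at
        the given DI equals ``target_called`` (bisection on the exact
        negative-binomial detection probabilities)."""
        thresholds = thresholds or CallingThresholds()
        if not 0 < target_called < len(panel):
            raise ValueError("target_called must be inside (0, panel size)")

        def expected_called(length_scale: float) -> float:
            scen = cls(di=di, length_scale=length_scale)
            return _expected_called(panel, depth_model, scen, thresholds)

        lo, hi = 5.0, 5000.0
        if expected_called(hi) < target_called:
            raise ValueError("target unreachable even with negligible degradation")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if expected_called(mid) < target_called:
                lo = mid
            else:
                hi = mid
        return cls(di=di, length_scale=0.5 * (lo + hi))


@dataclass(frozen=True)
class InhibitionScenario:
    """PCR-inhibitor gradient: a global depth-retention fraction looked
    up from a (inhibitor, dose) dose-response table."""

    inhibitor: str
    dose: float
    retention_table: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: INHIBITOR_RETENTION
    )

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.inhibitor not in self.retention_table:
            raise KeyError(
                f"unknown inhibitor {self.inhibitor!r}; have {sorted(self.retention_table)}"
            )

    def retention(self) -> float:
        table = self.retention_table[self.inhibitor]
        if self.dose in table:
            return table[self.dose]
        doses = sorted(table)
        if self.dose <= doses[0]:
            return table[doses[0]]
        if self.dose >= doses[-1]:
            return table[doses[-1]]
        return float(np.interp(self.dose, doses, [table[d] for d in doses]))


@dataclass(frozen=True)
class MixtureScenario:
    """Male-female mixture: full male signal plus stray female reads.

    Stray reads never carry the male truth's derived alleles; they enter
    the tally as off-target reads.  ``female_background_rate`` is the
    median stray-read count per locus per unit of female DNA;
    ``background_sigma`` spreads it lognormally across loci so a few
    loci attract most of the contamination, as seen in female-only
    specificity runs.
    """

    male_mass_ng: float = 1.0
    female_mass_ng: float = 0.0
    female_background_rate: float = 0.17
    background_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.male_mass_ng < 0 or self.female_mass_ng < 0:
            raise ValueError("masses must be >= 0")
        if self.female_background_rate < 0:
            raise ValueError("female_background_rate must be >= 0")


def FemaleScenario(female_mass_ng: float = 1.0) -> MixtureScenario:
    """Female-only negative control: no male template at all."""
    return MixtureScenario(male_mass_ng=0.0, female_mass_ng=female_mass_ng)


Scenario = DilutionScenario | DegradationScenario | InhibitionScenario | MixtureScenario


def _scenario_factors(scenario: Scenario | None) -> tuple[float, object, float]:
    """(male mass factor, survival function or None, female mass)."""
    if scenario is None:
        return 1.0, None, 0.0
    if isinstance(scenario, DilutionScenario):
        return scenario.mass_ng, None, 0.0
    if isinstance(scenario, DegradationScenario):
        return 1.0, scenario.survival, 0.0
    if isinstance(scenario, InhibitionScenario):
        return scenario.retention(), None, 0.0
    if isinstance(scenario, MixtureScenario):
        return scenario.male_mass_ng, None, scenario.female_mass_ng
    raise TypeError(f"unknown scenario {scenario!r}")


def _locus_means(
    panel: Sequence[Marker],
    depth_model: DepthModel,
    scenario: Scenario | None,
) -> np.ndarray:
    mass, survival, _ = _scenario_factors(scenario)
    effects = depth_model.locus_effects([m.name for m in panel])
    mu = np.array(
        [
            depth_model.baseline_mean_depth
            * depth_model.mass_scale
            * mass
            * effects[m.name]
            * (survival(m.amplicon_length) if survival is not None else 1.0)
            for m in panel
        ]
    )
    return mu


def _expected_called(
    panel: Sequence[Marker],
    depth_model: DepthModel,
    scenario: Scenario | None,
    thresholds: CallingThresholds,
) -> float:
    """Exact expected number of loci at or above the detection threshold."""
    mu = _locus_means(panel, depth_model, scenario)
    k = 1.0 / depth_model.dispersion
    p = k / (k + mu)
    return float(np.sum(stats.nbinom.sf(thresholds.detection - 1, k, p)))


def detection_probabilities(
    panel: Sequence[Marker],
    depth_model: DepthModel,
    scenario: Scenario | None,
    thresholds: CallingThresholds | None = None,
) -> np.ndarray:
    """Per-locus probability of reaching the detection threshold."""
    thresholds = thresholds or CallingThresholds()
    mu = _locus_means(panel, depth_model, scenario)
    k = 1.0 / depth_model.dispersion
    return stats.nbinom.sf(thresholds.detection - 1, k, k / (k + mu))


# ---------------------------------------------------------------------------
# Truth records and genotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated male: terminal haplogroup and the
    set of markers that are derived (exactly the root-path markers,
    before any mutation/error injection)."""

    sample_id: str
    haplogroup: str
    derived_markers: frozenset[str]

    def states(self, marker_names: Iterable[str]) -> dict[str, str]:
        return {
            name: ("DERIVED" if name in self.derived_markers else "ANCESTRAL")
            for name in marker_names
        }


def path_derived_markers(tree: HaplogroupTree, haplogroup: str) -> frozenset[str]:
    """Markers on the root path of a haplogroup (its derived set)."""
    return frozenset(
        m.name for node in tree.path_from_root(haplogroup) for m in node.markers
    )


# ---------------------------------------------------------------------------
# Panel fixture generation
# ---------------------------------------------------------------------------

@dataclass
class PanelFixture:
    markers: list[Marker]
    tree: HaplogroupTree

    @property
    def table(self) -> pd.DataFrame:
        return markers_to_table(self.markers)

    def write(self, path: str | Path) -> None:
        write_panel(self.markers, path)


def generate_panel_fixture(
    n_markers: int,
    clade_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    indel_fraction: float = 0.01,
    duplicate_rate: float = 0.02,
    shared_amplicon_rate: float = 0.05,
) -> PanelFixture:
    """Generate a synthetic panel whose labels form connected prefix
    families per clade.

    Amplicon lengths are drawn around 200 +- 12 bp and clipped to
    [120, 273] to echo the geometry of real short-amplicon panels.
    ``duplicate_rate`` controls how often a marker lands on an existing
    haplogroup node (several markers tagging one haplogroup);
    ``shared_amplicon_rate`` how often an amplicon covers two markers.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    mix = dict(clade_mix or DEFAULT_CLADE_MIX)
    if not mix:
        raise ValueError("clade_mix is empty")
    for clade, w in mix.items():
        parse_haplogroup_name(clade)
        if w < 0:
            raise ValueError(f"negative weight for clade {clade!r}")
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("clade weights sum to zero")
    rng = np.random.default_rng(seed)

    # Marker count per clade by largest remainder.
    clades = sorted(mix)
    quotas = {c: n_markers * mix[c] / total for c in clades}
    counts = {c: int(quotas[c]) for c in clades}
    short = n_markers - sum(counts.values())
    for c in sorted(clades, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1

    labels: list[str] = []
    for clade in clades:
        want = counts[clade]
        if want == 0:
            continue
        family = [clade]
        existing = {clade}
        while len(family) < want:
            parent = family[rng.integers(len(family))]
            if rng.random() < duplicate_rate and len(family) > 1:
                family.append(parent)  # second marker on an existing node
                continue
            last_is_digit = parent[-1].isdigit()
            for _ in range(50):
                if last_is_digit:
                    child = parent + "abcde"[rng.integers(5)]
                else:
                    child = parent + str(1 + rng.integers(5))
                if child not in existing:
                    break
            else:  # dense neighbourhood: extend deterministically
                suffix = 1
                child = parent + ("a" if last_is_digit else "1")
                while child in existing:
                    suffix += 1
                    child = parent + (
                        "abcdefghijklmnopqrstuvwxyz"[suffix % 26]
                        if last_is_digit
                        else str(suffix)
                    )
            existing.add(child)
            family.append(child)
        labels.extend(family)

    positions = rng.choice(
        np.arange(2_650_000, 26_600_000), size=len(labels), replace=False
    )
    markers: list[Marker] = []
    amp_idx = 0
    prev_amp: tuple[str, int] | None = None
    for i, label in enumerate(labels):
        is_indel = rng.random() < indel_fraction
        if is_indel:
            base = _BASES[rng.integers(4)]
            ins = "".join(_BASES[rng.integers(4)] for _ in range(1 + rng.integers(3)))
            anc, der = base, base + ins
            mclass = MarkerClass.INDEL
        else:
            anc = _BASES[rng.integers(4)]
            der = _BASES[(rng.integers(3) + _BASES.index(anc) + 1) % 4]
            mclass = MarkerClass.SNP
        if prev_amp is not None and rng.random() < shared_amplicon_rate:
            amp_id, amp_len = prev_amp
            prev_amp = None  # at most two markers per amplicon
        else:
            amp_idx += 1
            amp_id = f"AMP{amp_idx:05d}"
            amp_len = int(np.clip(round(rng.normal(200.0, 12.0)), 120, 273))
            prev_amp = (amp_id, amp_len)
        markers.append(
            Marker(
                name=f"SY{i + 1:05d}",
                position=int(positions[i]),
                ancestral_allele=anc,
                derived_allele=der,
                marker_class=mclass,
                haplogroup=label,
                amplicon_id=amp_id,
                amplicon_length=amp_len,
            )
        )
    return PanelFixture(markers=markers, tree=build_tree(markers))


# ---------------------------------------------------------------------------
# Population and pedigree simulation
# ---------------------------------------------------------------------------

def simulate_population(
    tree: HaplogroupTree,
    weights: Mapping[str, float],
    n: int,
    seed: int = 0,
    id_prefix: str = "S",
) -> list[TruthRecord]:
    """Draw n tree-consistent males from haplogroup sampling weights."""
    if n < 1:
        raise ValueError("n must be >= 1")
    missing = [lab for lab in weights if lab not in tree]
    if missing:
        raise KeyError(f"weights on labels absent from tree: {missing}")
    labels = sorted(weights)
    w = np.array([weights[lab] for lab in labels], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(labels), size=n, p=w / w.sum())
    derived_cache = {lab: path_derived_markers(tree, lab) for lab in labels}
    return [
        TruthRecord(
            sample_id=f"{id_prefix}{i + 1:04d}",
            haplogroup=labels[k],
            derived_markers=derived_cache[labels[k]],
        )
        for i, k in enumerate(draws)
    ]


def reference_pedigrees() -> PedigreeGraph:
    """Synthetic reconstruction of an 11-pedigree male-lineage study.

    The published diagrams are not redistributable, so these structures
    are synthetic stand-ins built to reproduce the published census
    exactly: 41 sampled males, 79 related pairs — 23 parent-offspring,
    12 full siblings, 24 2nd-, 13 3rd-, 4 4th-, 2 5th- and one
    6th-degree pair.  Unsampled connector males (deceased ancestors)
    appear with sampled=False.
    """
    records: list[tuple[str, str, str | None, bool]] = []

    def add(ped: str, ind: str, father: str | None, sampled: bool = True) -> None:
        records.append((ped, f"{ped}_{ind}", f"{ped}_{father}" if father else None, sampled))

    # P1: grandfather, three sons, five grandsons (9 sampled).
    add("P01", "GF", None)
    for f in ("F1", "F2", "F3"):
        add("P01", f, "GF")
    add("P01", "A", "F1"); add("P01", "B", "F1")
    add("P01", "C", "F2"); add("P01", "D", "F2")
    add("P01", "E", "F3")
    # P2: seven-generation chain, generation 4 unsampled (6 sampled).
    prev = None
    for g in range(7):
        add("P02", f"G{g}", prev, sampled=(g != 4))
        prev = f"G{g}"
    # P3: five-generation chain (5 sampled).
    prev = None
    for g in range(5):
        add("P03", f"G{g}", prev)
        prev = f"G{g}"
    # P4-P6: father and two sons (3 sampled each).
    for ped in ("P04", "P05", "P06"):
        add(ped, "F", None)
        add(ped, "S1", "F"); add(ped, "S2", "F")
    # P7: three brothers, father unsampled.
    add("P07", "F", None, sampled=False)
    for s in ("S1", "S2", "S3"):
        add("P07", s, "F")
    # P8: two brothers plus one brother's son; their father unsampled.
    add("P08", "F", None, sampled=False)
    add("P08", "A", "F"); add("P08", "B", "F")
    add("P08", "S", "A")
    # P9, P10: grandfather and grandson, middle generation unsampled.
    for ped in ("P09", "P10"):
        add(ped, "GF", None)
        add(ped, "F", "GF", sampled=False)
        add(ped, "S", "F")
    # P11: great-great-great-grandfather and descendant, middles unsampled.
    add("P11", "G0", None)
    for g in range(1, 4):
        add("P11", f"G{g}", f"G{g - 1}", sampled=False)
    add("P11", "G4", "G3")
    return PedigreeGraph.from_records(records)


def simulate_pedigree(
    tree: HaplogroupTree,
    founder_haplogroup: str | Mapping[str, str],
    pedigree: PedigreeGraph,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, TruthRecord]:
    """Propagate founder haplotypes down male pedigrees.

    Every male inherits his father's per-locus states; each meiosis
    flips each locus independently with probability ``mutation_rate``.
    ``founder_haplogroup`` is one label for all pedigrees or a mapping
    pedigree -> label.
    """
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must be in [0, 1]")
    founders = pedigree.founders()
    if isinstance(founder_haplogroup, str):
        founder_map = {ped: founder_haplogroup for ped in founders}
    else:
        founder_map = dict(founder_haplogroup)
        missing = set(founders) - set(founder_map)
        if missing:
            raise KeyError(f"no founder haplogroup for pedigrees {sorted(missing)}")
    for lab in set(founder_map.values()):
        if lab not in tree:
            raise KeyError(f"founder haplogroup {lab!r} not in tree")

    import networkx as nx

    rng = np.random.default_rng(seed)
    all_markers = [m.name for m in tree.markers]
    n_loci = len(all_markers)
    derived: dict[str, np.ndarray] = {}
    out: dict[str, TruthRecord] = {}
    for node in nx.topological_sort(pedigree.graph):
        ped = pedigree.pedigree_of(node)
        fathers = list(pedigree.graph.predecessors(node))
        if not fathers:
            hap = founder_map[ped]
            base = np.array(
                [name in path_derived_markers(tree, hap) for name in all_markers]
            )
        else:
            base = derived[fathers[0]].copy()
            if mutation_rate > 0:
                flips = rng.random(n_loci) < mutation_rate
                base ^= flips
        derived[node] = base
        out[node] = TruthRecord(
            sample_id=node,
            haplogroup=founder_map[ped],
            derived_markers=frozenset(
                name for name, d in zip(all_markers, base) if d
            ),
        )
    return out


# ---------------------------------------------------------------------------
# Read-count simulation
# ---------------------------------------------------------------------------

def simulate_readcounts(
    truth: Sequence[TruthRecord] | Mapping[str, TruthRecord],
    panel: Sequence[Marker],
    depth_model: DepthModel | None = None,
    scenario: Scenario | None = None,
    seed: int = 0,
) -> dict[str, list[LocusReadCount]]:
    """Per-locus read counts for each truth record under one scenario.

    Error-free male reads match the truth state; female stray reads (in
    mixture / female scenarios) are off-target and never carry the
    male's derived alleles.
    """
    depth_model = depth_model or DepthModel()
    records = list(truth.values()) if isinstance(truth, Mapping) else list(truth)
    rng = np.random.default_rng(seed)
    mass, survival, female_mass = _scenario_factors(scenario)
    effects = depth_model.locus_effects([m.name for m in panel])
    k = 1.0 / depth_model.dispersion
    bg_rate = (
        scenario.female_background_rate if isinstance(scenario, MixtureScenario) else 0.0
    )
    bg_sigma = (
        scenario.background_sigma if isinstance(scenario, MixtureScenario) else 0.0
    )
    out: dict[str, list[LocusReadCount]] = {}
    for rec in records:
        counts: list[LocusReadCount] = []
        for m in panel:
            mu = (
                depth_model.baseline_mean_depth
                * depth_model.mass_scale
                * mass
                * effects[m.name]
            )
            if survival is not None:
                mu *= survival(m.amplicon_length)
            male_depth = 0
            if mu > 0:
                lam = rng.gamma(shape=k, scale=mu / k)
                male_depth = int(rng.poisson(lam))
            other = 0
            if female_mass > 0 and bg_rate > 0:
                stray_mean = rng.lognormal(
                    mean=math.log(bg_rate * female_mass), sigma=bg_sigma
                )
                other = int(rng.poisson(stray_mean))
            is_derived = m.name in rec.derived_markers
            counts.append(
                LocusReadCount(
                    marker_name=m.name,
                    depth=male_depth + other,
                    ancestral_reads=0 if is_derived else male_depth,
                    derived_reads=male_depth if is_derived else 0,
                    other_reads=other,
                )
            )
        out[rec.sample_id] = counts
    return out


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(outdir: str | Path, seed: int = 0, force: bool = False) -> dict[str, Path]:
    """Write a miniature end-to-end dataset: panel, read counts for a
    two-population cohort, population map, a pedigree with its read
    counts, and the truth JSON.  Noise-free depths, so the pipeline
    recovers the truth exactly; byte-identical under the same seed."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    fixture = generate_panel_fixture(n_markers=60, seed=seed, duplicate_rate=0.0)
    tree = fixture.tree
    leaves = sorted(n.text for n in tree.nodes() if not n.children)
    weights = {lab: 1.0 for lab in leaves}
    cohort = simulate_population(tree, weights, n=30, seed=seed + 1)
    depth_model = DepthModel(baseline_mean_depth=2000.0, locus_sigma=0.2, effect_seed=seed + 2)
    counts = simulate_readcounts(cohort, fixture.markers, depth_model, seed=seed + 3)

    pops = {
        rec.sample_id: ("popA" if i < 15 else "popB") for i, rec in enumerate(cohort)
    }
    pedigree = reference_pedigrees()
    founder_labels = {
        ped: leaves[int(rng.integers(len(leaves)))] for ped in sorted(pedigree.founders())
    }
    ped_truth = simulate_pedigree(tree, founder_labels, pedigree, mutation_rate=0.0, seed=seed + 4)
    sampled = set(pedigree.sampled)
    ped_counts = simulate_readcounts(
        {k: v for k, v in ped_truth.items() if k in sampled},
        fixture.markers,
        depth_model,
        seed=seed + 5,
    )

    paths = {
        "panel": outdir / "panel.tsv",
        "counts": outdir / "counts.tsv",
        "pops": outdir / "pops.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "pedigree_counts": outdir / "pedigree_counts.tsv",
        "truth": outdir / "truth.json",
    }
    fixture.write(paths["panel"])
    counts_to_table(counts).to_csv(paths["counts"], sep="\t", index=False)
    pd.DataFrame(
        sorted(pops.items()), columns=["sample", "population"]
    ).to_csv(paths["pops"], sep="\t", index=False)
    pedigree.to_table().to_csv(paths["pedigree"], sep="\t", index=False)
    counts_to_table(ped_counts).to_csv(paths["pedigree_counts"], sep="\t", index=False)
    truth_doc = {
        "cohort": {rec.sample_id: rec.haplogroup for rec in cohort},
        "pedigree_founders": founder_labels,
        "pedigree_members": {k: v.haplogroup for k, v in sorted(ped_truth.items())},
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
    return paths


def bundle_checksums(paths: Mapping[str, Path]) -> dict[str, str]:
    """SHA-256 of each bundle file (determinism checks)."""
    return {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in sorted(paths.items())
    }


# ---------------------------------------------------------------------------
# VCF writing (round-trip oracle for the VCF extraction path)
# ---------------------------------------------------------------------------

def write_truth_vcf(
    truth: TruthRecord,
    panel: Sequence[Marker],
    path: str | Path,
    contig: str = "chrY",
) -> Path:
    """Write a minimal haploid GRCh38 chrY VCF for one truth record.

    REF is the ancestral allele and ALT the derived allele of each
    marker; the genotype is 1 where the truth is derived.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length=57227415>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{truth.sample_id}",
    ]
    for m in sorted(panel, key=lambda m: m.position):
        gt = "1" if m.name in truth.derived_markers else "0"
        lines.append(
            f"{contig}\t{m.position}\t{m.name}\t{m.ancestral_allele}\t"
            f"{m.derived_allele}\t.\tPASS\t.\tGT\t{gt}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
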