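"""Population- and pedigree-level statistics on haplogroup assignments.

Covers the multiplicity spectrum of a cohort, unbiased haplogroup
diversity H = N(1 - sum x_i^2)/(N - 1), level-truncated haplogroup
frequency spectra (HFS), pairwise Fst between populations (two-population
Nei G_ST on haploid haplogroup frequencies), PCA of population frequency
matrices, and genotype/haplogroup concordance across male pedigrees.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .calling import CallState, SampleProfile
from .inference import HaplogroupAssignment
from .panel import parse_haplogroup_name, truncate_to_level

#: Published multiplicity histogram of the 183 unrelated Liaoning Han
#: males genotyped with the 639-plex panel: 76 terminal haplogroups seen
#: once, 25 twice, 13 three times, 2 four times and 2 five times
#: (118 distinct lineages in all).
LIAONING_HAN_183_HISTOGRAM: dict[int, int] = {1: 76, 2: 25, 3: 13, 4: 2, 5: 2}


# ---------------------------------------------------------------------------
# Multiplicity spectrum and diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiplicitySpectrum:
    """Haplogroup occurrence counts n_k of a population sample."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = [k for k, n in self.counts.items() if n < 1]
        if bad:
            raise ValueError(f"non-positive counts for {bad}")

    @property
    def n(self) -> int:
        """Total sample size N = sum n_k."""
        return sum(self.counts.values())

    @property
    def n_lineages(self) -> int:
        return len(self.counts)

    @property
    def histogram(self) -> dict[int, int]:
        """Multiplicity m -> number of haplogroups observed exactly m times."""
        return dict(sorted(Counter(self.counts.values()).items()))

    @property
    def min_frequency(self) -> float:
        return min(self.counts.values()) / self.n

    @property
    def max_frequency(self) -> float:
        return max(self.counts.values()) / self.n

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int]) -> "MultiplicitySpectrum":
        """Build a spectrum with placeholder labels from a multiplicity
        histogram (diversity is invariant under relabelling)."""
        counts: dict[str, int] = {}
        for m, k in sorted(histogram.items()):
            for j in range(k):
                counts[f"L{m}x{j}"] = m
        return cls(counts)

    def summary(self) -> dict:
        return {
            "N": self.n,
            "n_lineages": self.n_lineages,
            "min_frequency": round(self.min_frequency, 4),
            "max_frequency": round(self.max_frequency, 4),
            "histogram": self.histogram,
        }


def multiplicity_summary(
    assignments: Sequence[HaplogroupAssignment | str],
) -> MultiplicitySpectrum:
    """Tally terminal haplogroups of a cohort into a spectrum."""
    if not assignments:
        raise ValueError("need at least one assignment")
    terminals = [
        a.terminal if isinstance(a, HaplogroupAssignment) else str(a)
        for a in assignments
    ]
    return MultiplicitySpectrum(dict(sorted(Counter(terminals).items())))


def haplogroup_diversity(spectrum: MultiplicitySpectrum) -> float:
    """Unbiased haplogroup diversity H = N(1 - sum x_i^2)/(N - 1).

    Equals the probability that two individuals sampled without
    replacement carry different haplogroups; 0 for a fixed sample,
    approaching 1 when every individual is unique.
    """
    n = spectrum.n
    if n < 2:
        raise ValueError(f"diversity undefined for N={n} (need N >= 2)")
    sum_sq = sum((k / n) ** 2 for k in spectrum.counts.values())
    return n * (1.0 - sum_sq) / (n - 1)


def diversity_report(spectrum: MultiplicitySpectrum) -> dict:
    """Diversity at full precision and at the conventional 4-decimal rendering."""
    h = haplogroup_diversity(spectrum)
    return {"H": h, "H_rounded": round(h, 4), **spectrum.summary()}


# ---------------------------------------------------------------------------
# Frequency spectra
# ---------------------------------------------------------------------------

@dataclass
class FrequencySpectrum:
    """Per-population haplogroup frequencies at one truncation level.

    ``table`` is a populations x haplogroups DataFrame whose rows sum
    to 1.  Cohorts are merged by simple row concatenation.
    """

    level: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(f"frequencies do not sum to 1 for populations {list(bad.index)}")

    def frequencies(self, population: str | None = None) -> dict[str, float]:
        if population is None:
            population = self.table.index[0]
        row = self.table.loc[population]
        return {k: float(v) for k, v in row.items() if v > 0}


def _terminals_of(assignments: Iterable[HaplogroupAssignment | str]) -> list[str]:
    return [
        a.terminal if isinstance(a, HaplogroupAssignment) else str(a)
        for a in assignments
    ]


def hfs(
    assignments: Sequence[HaplogroupAssignment | str]
    | Mapping[str, Sequence[HaplogroupAssignment | str]]
    | MultiplicitySpectrum,
    level: int,
    population: str = "pop",
) -> FrequencySpectrum:
    """Haplogroup frequency spectrum at a truncation level.

    Terminal labels are truncated to ``level`` components and tallied
    per population.  Accepts a single cohort (sequence or spectrum) or a
    mapping of population name to cohort.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    if isinstance(assignments, MultiplicitySpectrum):
        cohorts: dict[str, Counter] = {
            population: Counter(
                {
                    truncate_to_level(lab, level).text: 0
                    for lab in assignments.counts
                }
            )
        }
        for lab, k in assignments.counts.items():
            cohorts[population][truncate_to_level(lab, level).text] += k
    elif isinstance(assignments, Mapping):
        cohorts = {
            pop: Counter(truncate_to_level(t, level).text for t in _terminals_of(seq))
            for pop, seq in assignments.items()
        }
    else:
        cohorts = {
            population: Counter(
                truncate_to_level(t, level).text for t in _terminals_of(assignments)
            )
        }
    all_labels = sorted({lab for c in cohorts.values() for lab in c})
    rows = {
        pop: [c[lab] / sum(c.values()) for lab in all_labels]
        for pop, c in cohorts.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=all_labels)
    return FrequencySpectrum(level=level, table=table)


def clade_composition(
    assignments: Sequence[HaplogroupAssignment | str],
) -> dict[str, float]:
    """Fraction of samples per major clade (first name component)."""
    terminals = _terminals_of(assignments)
    if not terminals:
        raise ValueError("need at least one assignment")
    clades = Counter(parse_haplogroup_name(t).clade for t in terminals)
    total = sum(clades.values())
    return {c: k / total for c, k in sorted(clades.items())}


def render_percentages(fractions: Mapping[str, float]) -> dict[str, float]:
    """Conventional 1-decimal percent rendering of a fraction map."""
    return {k: round(100.0 * v, 1) for k, v in fractions.items()}


# ---------------------------------------------------------------------------
# Fst and PCA
# ---------------------------------------------------------------------------

def pairwise_fst(spectra: FrequencySpectrum | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fst between populations from haplogroup frequencies.

    Two-population Nei G_ST on haploid frequencies: with within-pair mean
    heterozygosity H_S = mean(1 - sum p^2) and total H_T computed from the
    unweighted mean frequency vector, Fst = (H_T - H_S)/H_T, defined as 0
    when both populations are fixed for the same haplogroup (H_T = 0).
    """
    table = spectra.table if isinstance(spectra, FrequencySpectrum) else spectra
    if len(table) < 2:
        raise ValueError("need at least two populations")
    sums = table.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValueError(f"frequencies do not sum to 1 for populations {list(bad.index)}")
    pops = list(table.index)
    freqs = table.to_numpy(dtype=float)
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q = freqs[i], freqs[j]
            h_s = 1.0 - 0.5 * (np.sum(p**2) + np.sum(q**2))
            pooled = 0.5 * (p + q)
            h_t = 1.0 - np.sum(pooled**2)
            fst = 0.0 if h_t == 0.0 else (h_t - h_s) / h_t
            out[i, j] = out[j, i] = fst
    return pd.DataFrame(out, index=pops, columns=pops)


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a population
    frequency-matrix decomposition."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_matrix(
    spectra: FrequencySpectrum | pd.DataFrame,
    n_components: int = 2,
) -> PCAResult:
    """PCA of the column-centred population x haplogroup frequency matrix.

    Deterministic up to component sign; signs are fixed so the largest-
    magnitude loading of each component is positive.
    """
    table = spectra.table if isinstance(spectra, FrequencySpectrum) else spectra
    n_pops = len(table)
    if n_pops < 3:
        raise ValueError(f"need at least 3 populations, got {n_pops}")
    if n_components > n_pops:
        raise ValueError(
            f"requested {n_components} components from {n_pops} populations"
        )
    x = table.to_numpy(dtype=float)
    centred = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = n_components
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for c in range(k):
        pivot = np.argmax(np.abs(loadings[:, c]))
        if loadings[pivot, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    var = s**2
    total = var.sum()
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comp_names),
        explained_variance_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def _ordinal(n: int) -> str:
    suffix = {1: "st", 2: "nd", 3: "rd"}.get(n if n < 20 else n % 10, "th")
    return f"{n}{suffix}"


@dataclass(frozen=True)
class RelatedPair:
    a: str
    b: str
    category: str
    degree: int


class PedigreeGraph:
    """Patrilineal pedigree: father -> son edges over male individuals.

    Unsampled connector males are allowed (``sampled=False``); the
    related-pair census is taken over sampled pairs only.  Relationship
    categories follow the forensic convention: parent-offspring and full
    siblings are 1st-degree (siblings censused in their own bucket);
    otherwise the degree is the meiosis count for lineal pairs and
    meioses minus one for collateral pairs.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("pedigree contains a cycle")
        for node in graph.nodes:
            if graph.in_degree(node) > 1:
                raise ValueError(f"individual {node!r} has more than one father")
        self.graph = graph

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str | None, bool]],
    ) -> "PedigreeGraph":
        """Build from (pedigree, individual, father-or-None, sampled) rows."""
        g = nx.DiGraph()
        rows = list(records)
        for ped, ind, father, sampled in rows:
            g.add_node(ind, pedigree=ped, sampled=bool(sampled))
        for ped, ind, father, sampled in rows:
            if father:
                if father not in g:
                    raise ValueError(f"father {father!r} of {ind!r} not declared")
                if g.nodes[father]["pedigree"] != ped:
                    raise ValueError(f"{ind!r}: father in a different pedigree")
                g.add_edge(father, ind)
        return cls(g)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PedigreeGraph":
        """Read a pedigree TSV: ``pedigree  individual  father  sampled``
        (empty father for founders; a non-empty ``mother`` column is
        rejected — transmission is Y-chromosomal)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if "mother" in df.columns and (df["mother"] != "").any():
            raise ValueError("female transmission edges are not allowed on the Y chromosome")
        return cls.from_records(
            (
                row.pedigree,
                row.individual,
                row.father or None,
                str(row.sampled).lower() in ("1", "true", "yes"),
            )
            for row in df.itertuples(index=False)
        )

    def to_table(self) -> pd.DataFrame:
        rows = [
            (
                self.graph.nodes[n]["pedigree"],
                n,
                next(iter(self.graph.predecessors(n)), ""),
                int(self.graph.nodes[n].get("sampled", True)),
            )
            for n in self.graph.nodes
        ]
        return pd.DataFrame(rows, columns=["pedigree", "individual", "father", "sampled"])

    @property
    def individuals(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def sampled(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.nodes[n].get("sampled", True)]

    def pedigree_of(self, individual: str) -> str:
        return self.graph.nodes[individual]["pedigree"]

    def founders(self) -> dict[str, str]:
        """Pedigree -> its unique paternal founder (in-degree 0)."""
        out: dict[str, str] = {}
        for n in nx.topological_sort(self.graph):
            if self.graph.in_degree(n) == 0:
                ped = self.pedigree_of(n)
                if ped in out:
                    raise ValueError(f"pedigree {ped!r} has multiple paternal founders")
                out[ped] = n
        return out

    def _ancestor_distances(self, individual: str) -> dict[str, int]:
        dist = {individual: 0}
        node, d = individual, 0
        while True:
            preds = list(self.graph.predecessors(node))
            if not preds:
                return dist
            node = preds[0]
            d += 1
            dist[node] = d

    def relationship(self, a: str, b: str) -> RelatedPair | None:
        """Classified relationship of a sampled pair, or None if unrelated."""
        if self.pedigree_of(a) != self.pedigree_of(b):
            return None
        da = self._ancestor_distances(a)
        db = self._ancestor_distances(b)
        common = set(da) & set(db)
        if not common:
            return None
        lca = min(common, key=lambda n: da[n] + db[n])
        ma, mb = da[lca], db[lca]
        if ma == 0 or mb == 0:
            degree = max(ma, mb)
            category = "parent-offspring" if degree == 1 else f"{_ordinal(degree)}-degree"
        elif ma == 1 and mb == 1:
            degree = 1
            category = "full-sibling"
        else:
            degree = ma + mb - 1
            category = f"{_ordinal(degree)}-degree"
        return RelatedPair(a, b, category, degree)

    def related_pairs(self) -> list[RelatedPair]:
        """All related sampled pairs, grouped by pedigree."""
        pairs: list[RelatedPair] = []
        by_ped: dict[str, list[str]] = {}
        for n in self.sampled:
            by_ped.setdefault(self.pedigree_of(n), []).append(n)
        for members in by_ped.values():
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    rel = self.relationship(members[i], members[j])
                    if rel is not None:
                        pairs.append(rel)
        return pairs

    def census(self) -> dict[str, int]:
        """Related-pair counts by category."""
        c = Counter(p.category for p in self.related_pairs())
        return dict(sorted(c.items()))


@dataclass
class PairConcordance:
    pair: RelatedPair
    co_called: int
    discordant_loci: tuple[str, ...]


@dataclass
class PedigreeConcordanceReport:
    pairs: list[PairConcordance]
    census: dict[str, int]
    mutation_events: int
    haplogroups_identical: dict[str, bool] = field(default_factory=dict)

    @property
    def n_related_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total_discordant(self) -> int:
        return sum(len(p.discordant_loci) for p in self.pairs)


def _states_of(profile: SampleProfile | Mapping[str, CallState | str]) -> dict[str, CallState]:
    if isinstance(profile, SampleProfile):
        return profile.states()
    return {k: CallState(v) for k, v in profile.items()}


def pedigree_concordance(
    profiles: Mapping[str, SampleProfile | Mapping[str, CallState | str]],
    pedigree: PedigreeGraph,
    assignments: Mapping[str, HaplogroupAssignment | str] | None = None,
) -> PedigreeConcordanceReport:
    """Genotype concordance across related pairs of male pedigrees.

    For every related sampled pair, counts co-called loci and loci with
    discordant called states.  Mutation events are the discordant loci
    summed over parent-offspring pairs (one meiosis each).  If terminal
    assignments are supplied, per-pedigree haplogroup identity is
    reported as well.
    """
    missing = [n for n in pedigree.sampled if n not in profiles]
    if missing:
        raise KeyError(f"no profile for pedigree members: {missing}")
    states = {n: _states_of(profiles[n]) for n in pedigree.sampled}
    pair_reports: list[PairConcordance] = []
    mutation_events = 0
    for pair in pedigree.related_pairs():
        sa, sb = states[pair.a], states[pair.b]
        co = 0
        disc: list[str] = []
        for name, st_a in sa.items():
            st_b = sb.get(name, CallState.NO_CALL)
            if st_a is CallState.NO_CALL or st_b is CallState.NO_CALL:
                continue
            co += 1
            if st_a is not st_b:
                disc.append(name)
        pair_reports.append(PairConcordance(pair, co, tuple(sorted(disc))))
        if pair.category == "parent-offspring":
            mutation_events += len(disc)
    hap_identical: dict[str, bool] = {}
    if assignments is not None:
        by_ped: dict[str, set[str]] = {}
        for n in pedigree.sampled:
            a = assignments[n]
            term = a.terminal if isinstance(a, HaplogroupAssignment) else str(a)
            by_ped.setdefault(pedigree.pedigree_of(n), set()).add(term)
        hap_identical = {ped: len(terms) == 1 for ped, terms in sorted(by_ped.items())}
    return PedigreeConcordanceReport(
        pairs=pair_reports,
        census=pedigree.census(),
        mutation_events=mutation_events,
        haplogroups_identical=hap_identical,
    )
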