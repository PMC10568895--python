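"""Panel model: markers, haplogroup nomenclature and the implied haplogroup tree.

A multiplexed Y-chromosome panel is a table of lineage-defining markers
(Y-SNPs and Y-Indels), each carrying the name of the haplogroup whose
derived allele it tags.  Haplogroup names follow the hierarchical ISOGG
convention: a single uppercase major-clade letter followed by alternating
digit runs and lowercase letter runs ("O2a2b1a1a1a1a1").  Because every
proper prefix of such a name (cut at a component boundary) names an
ancestral haplogroup, the set of labels in a panel induces a rooted tree
without any external phylogeny file; this module parses the names, builds
that tree, and summarises the panel's composition.
"""

from __future__ import annotations

import json
import logging
import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Name of the virtual root joining the major clades into one tree.
#: It carries no markers; every sample with no derived calls maps here.
ROOT_LABEL = "Y"

#: Columns of the panel TSV, in order.
PANEL_COLUMNS = (
    "marker",
    "chrom",
    "pos",
    "ancestral",
    "derived",
    "class",
    "haplogroup",
    "amplicon_id",
    "amplicon_len",
)


class MarkerClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class HaplogroupParseError(ValueError):
    """Raised when a haplogroup name violates the hierarchical grammar."""


@dataclass(frozen=True)
class HaplogroupLabel:
    """A parsed hierarchical haplogroup name.

    ``components`` alternate between letter runs and digit runs; the first
    component is always the single uppercase major-clade letter.  Joining
    the components reproduces ``text`` exactly.  ``provisional`` records a
    trailing ``~`` (ISOGG provisional branch), which is stripped from
    ``text`` during parsing.
    """

    text: str
    components: tuple[str, ...]
    provisional: bool = False

    @property
    def level(self) -> int:
        """Number of components; the depth of the label in name space."""
        return len(self.components)

    @property
    def clade(self) -> str:
        """Major-clade letter (first component)."""
        return self.components[0]

    def truncate(self, level: int) -> "HaplogroupLabel":
        """Label made of the first ``min(level, self.level)`` components."""
        if level < 1:
            raise ValueError(f"level must be >= 1, got {level}")
        if level >= self.level:
            return self
        comps = self.components[:level]
        return HaplogroupLabel(text="".join(comps), components=comps)

    def ancestors(self) -> Iterator["HaplogroupLabel"]:
        """Proper prefix ancestors, shallowest first (level 1 .. level-1)."""
        for k in range(1, self.level):
            yield self.truncate(k)

    def is_prefix_of(self, other: "HaplogroupLabel") -> bool:
        return (
            other.level >= self.level
            and other.components[: self.level] == self.components
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


def parse_haplogroup_name(text: str) -> HaplogroupLabel:
    """Parse a hierarchical haplogroup name into its components.

    The grammar: one uppercase letter, then alternating digit runs and
    lowercase letter runs.  A single trailing ``~`` marks a provisional
    branch and is accepted and recorded.  Anything else (leading digit,
    whitespace, punctuation, uppercase letters past the first position)
    raises :class:`HaplogroupParseError` naming the offending character.
    """
    if not isinstance(text, str):
        raise HaplogroupParseError(f"haplogroup name must be a string, got {type(text).__name__}")
    if not text:
        raise HaplogroupParseError("empty haplogroup name")
    provisional = text.endswith("~")
    core = text[:-1] if provisional else text
    if not core:
        raise HaplogroupParseError(f"{text!r}: nothing before the provisional '~'")
    for i, ch in enumerate(core):
        if not ch.isascii() or not ch.isalnum():
            raise HaplogroupParseError(
                f"{text!r}: invalid character {ch!r} at position {i}"
            )
    head = core[0]
    if head.isdigit():
        raise HaplogroupParseError(f"{text!r}: leading digit {head!r}")
    if not head.isupper():
        raise HaplogroupParseError(
            f"{text!r}: must start with an uppercase clade letter, found {head!r}"
        )
    components = [head]
    i = 1
    expect_digit = True
    while i < len(core):
        ch = core[i]
        if expect_digit:
            if not ch.isdigit():
                raise HaplogroupParseError(
                    f"{text!r}: expected a digit at position {i}, found {ch!r}"
                )
            j = i
            while j < len(core) and core[j].isdigit():
                j += 1
        else:
            if not (ch.isalpha() and ch.islower()):
                raise HaplogroupParseError(
                    f"{text!r}: expected a lowercase letter at position {i}, found {ch!r}"
                )
            j = i
            while j < len(core) and core[j].isalpha():
                if not core[j].islower():
                    raise HaplogroupParseError(
                        f"{text!r}: uppercase letter {core[j]!r} at position {j}"
                    )
                j += 1
        components.append(core[i:j])
        i = j
        expect_digit = not expect_digit
    return HaplogroupLabel(text=core, components=tuple(components), provisional=provisional)


def truncate_to_level(label: HaplogroupLabel | str, level: int) -> HaplogroupLabel:
    """Truncate a label to at most ``level`` components (idempotent)."""
    if isinstance(label, str):
        label = parse_haplogroup_name(label)
    return label.truncate(level)


@dataclass(frozen=True)
class Marker:
    """One panel locus: a Y-SNP or Y-Indel tagging a haplogroup.

    Coordinates are 1-based chrY positions on GRCh38.  For Indels the
    ancestral/derived alleles are the full reference and alternate
    spanning sequences, so calls can use sequence equality.
    """

    name: str
    position: int
    ancestral_allele: str
    derived_allele: str
    marker_class: MarkerClass
    haplogroup: str
    amplicon_id: str
    amplicon_length: int

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"marker {self.name}: position must be positive")
        if self.ancestral_allele == self.derived_allele:
            raise ValueError(f"marker {self.name}: ancestral and derived alleles are equal")
        if not (100 <= self.amplicon_length <= 400):
            raise ValueError(
                f"marker {self.name}: amplicon length {self.amplicon_length} outside [100, 400]"
            )


@dataclass
class HaplogroupNode:
    """Node of the haplogroup tree: one label plus its markers."""

    label: HaplogroupLabel | None  # None only for the virtual root
    text: str
    parent: "HaplogroupNode | None" = None
    children: list["HaplogroupNode"] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)

    @property
    def is_root(self) -> bool:
        return self.label is None

    @property
    def level(self) -> int:
        return 0 if self.label is None else self.label.level

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HaplogroupNode({self.text}, markers={len(self.markers)})"


class HaplogroupTree:
    """Rooted tree of haplogroup labels, built from the name grammar.

    Major clades hang off a virtual root named ``Y``.  Every non-root
    node's parent is the longest proper component-prefix of its label
    present in the panel (missing intermediate labels are bridged).
    """

    def __init__(self, root: HaplogroupNode, nodes: dict[str, HaplogroupNode]):
        self.root = root
        self._nodes = nodes  # excludes the virtual root
        self._marker_to_node: dict[str, HaplogroupNode] = {}
        for node in nodes.values():
            for m in node.markers:
                self._marker_to_node[m.name] = node

    def __len__(self) -> int:
        """Number of haplogroup nodes (virtual root excluded)."""
        return len(self._nodes)

    def __contains__(self, text: str) -> bool:
        return text in self._nodes

    def node(self, text: str) -> HaplogroupNode:
        if text == ROOT_LABEL:
            return self.root
        try:
            return self._nodes[text]
        except KeyError:
            raise KeyError(f"haplogroup {text!r} not in tree") from None

    def labels(self) -> list[str]:
        return list(self._nodes)

    def nodes(self) -> Iterator[HaplogroupNode]:
        return iter(self._nodes.values())

    @property
    def markers(self) -> list[Marker]:
        return [m for node in self._nodes.values() for m in node.markers]

    def marker_node(self, marker_name: str) -> HaplogroupNode:
        try:
            return self._marker_to_node[marker_name]
        except KeyError:
            raise KeyError(f"marker {marker_name!r} not in panel") from None

    def path_from_root(self, text: str) -> list[HaplogroupNode]:
        """Nodes from the shallowest ancestor down to ``text`` (root excluded)."""
        node = self.node(text)
        path: list[HaplogroupNode] = []
        while node is not None and not node.is_root:
            path.append(node)
            node = node.parent
        path.reverse()
        return path

    def descendants(self, text: str) -> Iterator[HaplogroupNode]:
        stack = list(self.node(text).children)
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def to_newick(self) -> str:
        """Newick string with node labels and no branch lengths."""

        def fmt(node: HaplogroupNode) -> str:
            if not node.children:
                return node.text
            inner = ",".join(fmt(c) for c in sorted(node.children, key=lambda n: n.text))
            return f"({inner}){node.text}"

        return fmt(self.root) + ";"

    def to_dict(self) -> dict:
        """Nested dict form (label, markers, children) for JSON export."""

        def conv(node: HaplogroupNode) -> dict:
            return {
                "label": node.text,
                "markers": [m.name for m in node.markers],
                "children": [
                    conv(c) for c in sorted(node.children, key=lambda n: n.text)
                ],
            }

        return conv(self.root)


def build_tree(markers: Iterable[Marker]) -> HaplogroupTree:
    """Build the haplogroup tree implied by the markers' labels.

    Markers sharing a label share one node.  A label whose immediate
    prefix parent is absent from the panel links to the nearest present
    prefix ancestor, or to the virtual root.  Duplicate marker names are
    rejected.
    """
    markers = list(markers)
    seen: dict[str, int] = {}
    for m in markers:
        seen[m.name] = seen.get(m.name, 0) + 1
    dups = sorted(name for name, k in seen.items() if k > 1)
    if dups:
        raise ValueError(f"duplicate marker names: {', '.join(dups)}")

    by_label: dict[str, list[Marker]] = {}
    parsed: dict[str, HaplogroupLabel] = {}
    for m in markers:
        lab = parse_haplogroup_name(m.haplogroup)
        parsed.setdefault(lab.text, lab)
        by_label.setdefault(lab.text, []).append(m)

    root = HaplogroupNode(label=None, text=ROOT_LABEL)
    nodes: dict[str, HaplogroupNode] = {}
    for text in sorted(parsed, key=lambda t: (parsed[t].level, t)):
        lab = parsed[text]
        parent = root
        for k in range(lab.level - 1, 0, -1):
            anc = "".join(lab.components[:k])
            if anc in nodes:
                parent = nodes[anc]
                break
        node = HaplogroupNode(label=lab, text=text, parent=parent, markers=by_label[text])
        parent.children.append(node)
        nodes[text] = node
    return HaplogroupTree(root, nodes)


@dataclass
class PanelSummary:
    """Composition summary of a panel: marker/haplogroup counts, clade mix,
    and amplicon-length statistics over distinct amplicons."""

    marker_count: int
    snp_count: int
    indel_count: int
    haplogroup_count: int
    clade_marker_counts: dict[str, int]
    clade_marker_fractions: dict[str, float]
    amplicon_count: int
    amplicon_length_min: int
    amplicon_length_max: int
    amplicon_length_mean: float
    amplicon_length_sd: float

    def clade_fraction(self, clades: Iterable[str]) -> float:
        """Combined marker fraction of the given major clades."""
        return sum(self.clade_marker_fractions.get(c, 0.0) for c in clades)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.__dict__, indent=indent, sort_keys=False)


def summarize_panel(tree: HaplogroupTree) -> PanelSummary:
    markers = tree.markers
    if not markers:
        raise ValueError("empty panel")
    clade_counts: dict[str, int] = {}
    for m in markers:
        clade = parse_haplogroup_name(m.haplogroup).clade
        clade_counts[clade] = clade_counts.get(clade, 0) + 1
    total = len(markers)
    fractions = {c: n / total for c, n in sorted(clade_counts.items())}
    amp_lengths: dict[str, int] = {}
    for m in markers:
        prev = amp_lengths.setdefault(m.amplicon_id, m.amplicon_length)
        if prev != m.amplicon_length:
            raise ValueError(
                f"amplicon {m.amplicon_id}: inconsistent lengths {prev} and {m.amplicon_length}"
            )
    lengths = list(amp_lengths.values())
    return PanelSummary(
        marker_count=total,
        snp_count=sum(1 for m in markers if m.marker_class is MarkerClass.SNP),
        indel_count=sum(1 for m in markers if m.marker_class is MarkerClass.INDEL),
        haplogroup_count=len(tree),
        clade_marker_counts=dict(sorted(clade_counts.items())),
        clade_marker_fractions=fractions,
        amplicon_count=len(lengths),
        amplicon_length_min=min(lengths),
        amplicon_length_max=max(lengths),
        amplicon_length_mean=float(statistics.fmean(lengths)),
        amplicon_length_sd=float(statistics.stdev(lengths)) if len(lengths) > 1 else 0.0,
    )


def read_panel(path: str | Path) -> list[Marker]:
    """Read a panel TSV (fixed header; unknown extra columns are ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in PANEL_COLUMNS]
    if extra:
        logger.warning("panel file %s: ignoring extra columns %s", path, extra)
    markers = []
    for row in df.to_dict("records"):
        chrom = str(row["chrom"])
        if chrom not in ("chrY", "Y"):
            raise ValueError(f"marker {row['marker']}: chrom must be chrY, got {chrom!r}")
        markers.append(
            Marker(
                name=str(row["marker"]),
                position=int(row["pos"]),
                ancestral_allele=str(row["ancestral"]),
                derived_allele=str(row["derived"]),
                marker_class=MarkerClass(str(row["class"]).upper()),
                haplogroup=str(row["haplogroup"]),
                amplicon_id=str(row["amplicon_id"]),
                amplicon_length=int(row["amplicon_len"]),
            )
        )
    return markers


def markers_to_table(markers: Sequence[Marker]) -> pd.DataFrame:
    """Panel TSV table (schema of :data:`PANEL_COLUMNS`) for a marker list."""
    return pd.DataFrame(
        {
            "marker": [m.name for m in markers],
            "chrom": "chrY",
            "pos": [m.position for m in markers],
            "ancestral": [m.ancestral_allele for m in markers],
            "derived": [m.derived_allele for m in markers],
            "class": [m.marker_class.value for m in markers],
            "haplogroup": [m.haplogroup for m in markers],
            "amplicon_id": [m.amplicon_id for m in markers],
            "amplicon_len": [m.amplicon_length for m in markers],
        }
    )


def write_panel(markers: Sequence[Marker], path: str | Path) -> None:
    markers_to_table(markers).to_csv(path, sep="\t", index=False)
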