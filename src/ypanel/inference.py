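"""Terminal-haplogroup inference by tree traversal over derived calls.

A sample's terminal haplogroup is the deepest tree node with at least one
derived marker whose whole root path is supported: every node on the path
either carries a derived call or (under the default imputation policy)
had all of its markers drop out.  An ancestral call at a node vetoes the
node and everything below it.  Derived calls that end up off the chosen
path are reported and downgrade confidence; candidates in disjoint clades
produce a CONFLICTED assignment with a deterministic tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .calling import CallState, CallStatus, SampleProfile
from .panel import ROOT_LABEL, HaplogroupNode, HaplogroupTree, build_tree

logger = logging.getLogger(__name__)


class Confidence(str, Enum):
    CLEAN = "CLEAN"
    IMPUTED = "IMPUTED"
    CONFLICTED = "CONFLICTED"


@dataclass(frozen=True)
class InferencePolicy:
    """Rules applied during traversal.

    ``impute_dropout``: a path node whose markers all dropped out does not
    block deeper derived evidence (a deeper derived marker rescues the
    path).  ``use_review_calls``: calls in the detection..analysis review
    window count as their state; mixed-flagged calls are always treated
    as no-calls.
    """

    impute_dropout: bool = True
    use_review_calls: bool = True


DEFAULT_POLICY = InferencePolicy()


@dataclass
class PathStep:
    """One node of the supporting path with its derived markers."""

    label: str
    derived_markers: tuple[str, ...]


@dataclass
class HaplogroupAssignment:
    sample_id: str
    terminal: str
    derived_path: tuple[PathStep, ...]
    off_path_derived: tuple[str, ...]
    dropped_on_path: tuple[str, ...]
    confidence: Confidence
    tied_with: tuple[str, ...] = ()

    @property
    def n_path_markers(self) -> int:
        return sum(len(s.derived_markers) for s in self.derived_path)


def _effective_states(
    profile: SampleProfile | Mapping[str, CallState | str],
    policy: InferencePolicy,
) -> dict[str, CallState]:
    """Normalise input to marker -> effective CallState."""
    if isinstance(profile, SampleProfile):
        states: dict[str, CallState] = {}
        for name, call in profile.calls.items():
            if call.status is CallStatus.MIXED_FLAG:
                logger.debug("marker %s: mixed flag treated as no-call", name)
                states[name] = CallState.NO_CALL
            elif call.status is CallStatus.REVIEW and not policy.use_review_calls:
                states[name] = CallState.NO_CALL
            else:
                states[name] = call.state
        return states
    return {name: CallState(state) for name, state in profile.items()}


def infer_haplogroup(
    profile: SampleProfile | Mapping[str, CallState | str],
    tree: HaplogroupTree,
    policy: InferencePolicy = DEFAULT_POLICY,
    sample_id: str | None = None,
) -> HaplogroupAssignment:
    """Assign the deepest consistent terminal haplogroup to a profile.

    ``profile`` may be a :class:`SampleProfile` or a plain mapping of
    marker name to state (markers missing from a mapping are treated as
    no-calls).  See the module docstring for the traversal rules.
    """
    if sample_id is None:
        sample_id = profile.sample_id if isinstance(profile, SampleProfile) else "sample"
    states = _effective_states(profile, policy)

    # Tally calls per node.
    n_derived: dict[str, int] = {}
    n_ancestral: dict[str, int] = {}
    for name in states:
        tree.marker_node(name)  # raises on unknown markers
    for node in tree.nodes():
        d = a = 0
        for m in node.markers:
            s = states.get(m.name, CallState.NO_CALL)
            if s is CallState.DERIVED:
                d += 1
            elif s is CallState.ANCESTRAL:
                a += 1
        n_derived[node.text] = d
        n_ancestral[node.text] = a

    # Depth-first walk from the virtual root collecting reachable
    # derived-supported candidates.  A node is passable when derived-
    # supported, or fully dropped out under the imputation policy;
    # an ancestral call vetoes the node and its subtree.
    candidates: list[HaplogroupNode] = []
    stack: list[HaplogroupNode] = list(tree.root.children)
    while stack:
        node = stack.pop()
        if n_ancestral[node.text] > 0:
            continue  # veto: subtree unreachable
        supported = n_derived[node.text] > 0
        if supported:
            candidates.append(node)
        if supported or policy.impute_dropout:
            stack.extend(node.children)

    if not candidates:
        off_path = tuple(
            sorted(
                m.name
                for node in tree.nodes()
                for m in node.markers
                if states.get(m.name, CallState.NO_CALL) is CallState.DERIVED
            )
        )
        confidence = Confidence.CLEAN if not off_path else Confidence.IMPUTED
        return HaplogroupAssignment(
            sample_id=sample_id,
            terminal=ROOT_LABEL,
            derived_path=(),
            off_path_derived=off_path,
            dropped_on_path=(),
            confidence=confidence,
        )

    # Maximal candidates: those without a deeper candidate below them.
    cand_set = {n.text for n in candidates}
    non_maximal: set[str] = set()
    for node in candidates:
        parent = node.parent
        while parent is not None and not parent.is_root:
            if parent.text in cand_set:
                non_maximal.add(parent.text)
            parent = parent.parent
    maximal = [n for n in candidates if n.text not in non_maximal]

    def path_score(node: HaplogroupNode) -> int:
        return sum(n_derived[p.text] for p in tree.path_from_root(node.text))

    ranked = sorted(maximal, key=lambda n: (-path_score(n), -n.level, n.text))
    terminal = ranked[0]
    best_key = (path_score(terminal), terminal.level)
    tied = tuple(
        n.text for n in ranked[1:] if (path_score(n), n.level) == best_key
    )

    path_nodes = tree.path_from_root(terminal.text)
    path_set = {n.text for n in path_nodes}
    derived_path = tuple(
        PathStep(
            label=n.text,
            derived_markers=tuple(
                m.name
                for m in n.markers
                if states.get(m.name, CallState.NO_CALL) is CallState.DERIVED
            ),
        )
        for n in path_nodes
    )
    dropped = tuple(n.text for n in path_nodes if n_derived[n.text] == 0)
    off_path = tuple(
        sorted(
            m.name
            for node in tree.nodes()
            if node.text not in path_set
            for m in node.markers
            if states.get(m.name, CallState.NO_CALL) is CallState.DERIVED
        )
    )
    if len(maximal) > 1:
        confidence = Confidence.CONFLICTED
    elif off_path or dropped:
        confidence = Confidence.IMPUTED
    else:
        confidence = Confidence.CLEAN
    return HaplogroupAssignment(
        sample_id=sample_id,
        terminal=terminal.text,
        derived_path=derived_path,
        off_path_derived=off_path,
        dropped_on_path=dropped,
        confidence=confidence,
        tied_with=tied,
    )


def reduced_panel_inference(
    profile: SampleProfile | Mapping[str, CallState | str],
    tree: HaplogroupTree,
    marker_subset: Iterable[str],
    policy: InferencePolicy = DEFAULT_POLICY,
    sample_id: str | None = None,
) -> HaplogroupAssignment:
    """Infer as if only ``marker_subset`` had been genotyped.

    The tree is rebuilt from the subset's markers, so with error-free
    calls the result is always an ancestor-or-equal of the full-panel
    terminal — this is how a lower-resolution panel behaves.
    """
    subset = set(marker_subset)
    unknown = subset - {m.name for m in tree.markers}
    if unknown:
        raise KeyError(f"markers not in panel: {sorted(unknown)}")
    if sample_id is None:
        sample_id = profile.sample_id if isinstance(profile, SampleProfile) else "sample"
    if not subset:
        return HaplogroupAssignment(
            sample_id=sample_id,
            terminal=ROOT_LABEL,
            derived_path=(),
            off_path_derived=(),
            dropped_on_path=(),
            confidence=Confidence.CLEAN,
        )
    sub_tree = build_tree(m for m in tree.markers if m.name in subset)
    if isinstance(profile, SampleProfile):
        restricted: Mapping[str, CallState | str] = {
            name: call.state
            for name, call in profile.calls.items()
            if name in subset and call.status is not CallStatus.MIXED_FLAG
        }
    else:
        restricted = {name: s for name, s in profile.items() if name in subset}
    return infer_haplogroup(restricted, sub_tree, policy=policy, sample_id=sample_id)


def derived_marker_table(
    assignments: Sequence[HaplogroupAssignment],
    tree: HaplogroupTree,
) -> dict[str, int]:
    """Per-node sample counts of the hierarchical derived-marker report.

    Each sample increments every node on its root-to-terminal path, so
    counts are monotone non-increasing from ancestor to descendant.
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    counts = {text: 0 for text in tree.labels()}
    for a in assignments:
        if a.terminal == ROOT_LABEL:
            continue
        for node in tree.path_from_root(a.terminal):
            counts[node.text] += 1
    return counts
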