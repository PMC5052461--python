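"""Toy medical lexicon with ontology structure and information content.

The lexicon mirrors, at desk scale, the structure of a clinical terminology:
terms map to concepts, concepts carry one or more coarse semantic groups
(disease, drug, device, procedure), and concepts are linked by is-a parent
edges forming a rooted directed acyclic graph.  Each term carries a corpus
frequency; the information content of a concept is

    IC(c) = -ln( n(c) / n(root) )

where ``n(c)`` is the concept's own corpus count plus the counts of all of
its descendants.  Because a descendant's descendant set is contained in its
ancestor's, IC is monotonically nondecreasing along every root-to-leaf path,
which makes it a well-behaved specificity score for search terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .config import SEMANTIC_GROUPS
from .errors import ConfigError

ROOT = "ROOT"


@dataclass
class Lexicon:
    """Term -> concept mapping over a rooted concept DAG.

    Parameters
    ----------
    term_concepts:
        Mapping from each term string to the (non-empty) tuple of concept
        ids it denotes.
    concept_parents:
        Mapping concept id -> tuple of parent concept ids; the root has no
        entry (or an empty tuple).
    concept_groups:
        Mapping concept id -> tuple of semantic groups (subset of
        disease/drug/device/procedure).  The root and purely structural
        concepts may carry no group.
    term_freq:
        Corpus frequency (document-level count) per term.
    """

    term_concepts: dict[str, tuple[str, ...]]
    concept_parents: dict[str, tuple[str, ...]]
    concept_groups: dict[str, tuple[str, ...]]
    term_freq: dict[str, int]

    _graph: nx.DiGraph = field(init=False, repr=False)
    _concept_ic: dict[str, float] = field(init=False, repr=False)
    _term_ic: dict[str, float] = field(init=False, repr=False)
    _term_groups: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_node(ROOT)
        for child, parents in self.concept_parents.items():
            for p in parents:
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigError("concept parent links contain a cycle")
        unreachable = set(g.nodes) - set(nx.descendants(g, ROOT)) - {ROOT}
        if unreachable:
            raise ConfigError(f"concepts unreachable from root: {sorted(unreachable)[:5]}")
        for term, concepts in self.term_concepts.items():
            if not concepts:
                raise ConfigError(f"term {term!r} maps to no concept")
            for c in concepts:
                if c not in g:
                    raise ConfigError(f"term {term!r} maps to unknown concept {c!r}")
        for group_tuple in self.concept_groups.values():
            for grp in group_tuple:
                if grp not in SEMANTIC_GROUPS:
                    raise ConfigError(f"unknown semantic group {grp!r}")
        self._graph = g
        self._compute_ic()
        self._term_groups = {
            term: frozenset(
                grp for c in concepts for grp in self.concept_groups.get(c, ())
            )
            for term, concepts in self.term_concepts.items()
        }

    # -- information content -------------------------------------------------

    def _own_count(self, concept: str) -> int:
        return sum(
            self.term_freq.get(t, 0)
            for t, cs in self.term_concepts.items()
            if concept in cs
        )

    def _compute_ic(self) -> None:
        own = {c: self._own_count(c) for c in self._graph.nodes}
        agg: dict[str, int] = {}
        for c in self._graph.nodes:
            desc = nx.descendants(self._graph, c)
            agg[c] = own[c] + sum(own[d] for d in desc)
        total = agg[ROOT]
        if total <= 0:
            raise ConfigError("lexicon has zero total corpus frequency")
        self._concept_ic = {
            c: (math.inf if n == 0 else -math.log(n / total)) for c, n in agg.items()
        }
        self._aggregated_freq = agg
        # A term's IC is the IC of its most specific concept.
        self._term_ic = {
            term: max(self._concept_ic[c] for c in concepts)
            for term, concepts in self.term_concepts.items()
        }

    def concept_ic(self, concept: str) -> float:
        return self._concept_ic[concept]

    def aggregated_frequency(self, concept: str) -> int:
        """Concept corpus count including all descendants."""
        return self._aggregated_freq[concept]

    def information_content(self, term: str) -> float:
        """IC of a term; raises KeyError for terms outside the lexicon."""
        return self._term_ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.term_concepts

    # -- semantic groups -----------------------------------------------------

    def term_semantic_groups(self, term: str) -> frozenset[str]:
        """Semantic groups a term belongs to (empty set if unmapped)."""
        return self._term_groups.get(term, frozenset())

    def terms_in_groups(self, groups) -> set[str]:
        gs = set(groups)
        return {t for t, tg in self._term_groups.items() if tg & gs}

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_concepts)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "term_concepts": {t: list(c) for t, c in self.term_concepts.items()},
            "concept_parents": {c: list(p) for c, p in self.concept_parents.items()},
            "concept_groups": {c: list(g) for c, g in self.concept_groups.items()},
            "term_freq": dict(self.term_freq),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Lexicon":
        return cls(
            term_concepts={t: tuple(c) for t, c in data["term_concepts"].items()},
            concept_parents={c: tuple(p) for c, p in data["concept_parents"].items()},
            concept_groups={c: tuple(g) for c, g in data["concept_groups"].items()},
            term_freq={t: int(f) for t, f in data["term_freq"].items()},
        )
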