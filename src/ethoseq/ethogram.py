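"""Ethogram assembly: behavior categories, frequencies, graph export.

A behavior is operationally *aggressive* when its statistically supported
modal consequence is the immediate ending of the interaction (the partner
flees): the (behavior -> end) cell must be significantly over-represented
AND ``end`` must be the behavior's most likely transition target.  Both
conditions are required; behaviors with no statistically supported
transitions default to nonaggressive (absence of evidence of aggression).

Mounting is categorized on its own (it occurs in both courtship and
same-sex contexts), and ``end`` is terminal.  The non-contact approach
``proximity`` is never an aggression candidate: in an approach-then-leave
sequence it is the initiator who withdraws, not the partner who flees, so
a frequent proximity -> end transition carries no aggressive meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .event_log import BehaviorEvent, Bout, PHYSICAL_BEHAVIORS
from .transitions import MarkovModel, ResidualTable

CATEGORIES = ("aggressive", "nonaggressive", "mounting", "terminal")

_CATEGORY_COLOR = {
    "aggressive": "red",
    "nonaggressive": "blue",
    "mounting": "purple",
    "terminal": "gray",
}


@dataclass
class FrequencyTable:
    """Behavior counts plus two proportion bases.

    ``proportion_physical`` is each physical behavior's share of all
    initiated physical behaviors; ``proximity_only_share`` is the share of
    initiated interactions (bouts) consisting solely of an approach.
    """

    counts: Dict[str, int]
    proportion_physical: Dict[str, float]
    proximity_only_share: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"behavior": b, "count": self.counts.get(b, 0),
                 "proportion_physical": self.proportion_physical.get(b, float("nan"))}
                for b in sorted(self.counts)]
        return pd.DataFrame(rows)


@dataclass
class EthogramModel:
    markov: MarkovModel
    residuals: ResidualTable
    frequency: FrequencyTable
    category: Dict[str, str]

    @property
    def aggressive_behaviors(self) -> Tuple[str, ...]:
        return tuple(sorted(b for b, c in self.category.items() if c == "aggressive"))

    def summary_frame(self) -> pd.DataFrame:
        df = self.frequency.to_frame()
        df["category"] = [self.category.get(b, "") for b in df["behavior"]]
        return df


def classify_behaviors(markov: MarkovModel, residuals: ResidualTable) -> Dict[str, str]:
    """Assign each behavior its ethogram category.

    Candidates for the aggressive/nonaggressive distinction are the
    physical behaviors other than ``mount``.  A candidate is aggressive
    iff its transition into ``end`` is significant with positive residual
    and ``end`` is its modal target; otherwise nonaggressive.  A behavior
    never observed as a source cannot show evidence of aggression and is
    classified nonaggressive with a warning.
    """
    if markov.row_labels != residuals.row_labels or markov.col_labels != residuals.col_labels:
        raise ValueError("markov and residual labels disagree")
    category: Dict[str, str] = {}
    for b in markov.row_labels:
        if b == "mount":
            category[b] = "mounting"
            continue
        if b == "proximity":
            category[b] = "nonaggressive"
            continue
        i = markov.row_labels.index(b)
        if not markov.defined[i]:
            warnings.warn(f"behavior {b!r} never observed as a source; "
                          "classified nonaggressive", stacklevel=2)
            category[b] = "nonaggressive"
            continue
        _, resid, sig = residuals.cell(b, "end")
        modal = markov.modal_target(b) == "end"
        category[b] = "aggressive" if (sig and resid > 0 and modal) else "nonaggressive"
    category["end"] = "terminal"
    return category


def behavior_frequencies(events: Sequence[BehaviorEvent],
                         bouts: Optional[Sequence[Bout]] = None) -> FrequencyTable:
    """Tally behavior counts and the two reporting proportions.

    Counts cover every scored (non-synthetic) event.  Physical-behavior
    proportions are computed over initiated physical behaviors only.  The
    proximity-only share requires the bout segmentation and is None when
    ``bouts`` is not given.
    """
    counts: Dict[str, int] = {}
    for ev in events:
        if ev.synthetic_end:
            continue
        counts[ev.behavior] = counts.get(ev.behavior, 0) + 1
    for b in PHYSICAL_BEHAVIORS + ("proximity",):
        counts.setdefault(b, 0)

    n_physical = sum(counts.get(b, 0) for b in PHYSICAL_BEHAVIORS)
    prop = {b: (counts.get(b, 0) / n_physical if n_physical else float("nan"))
            for b in PHYSICAL_BEHAVIORS}

    prox_share: Optional[float] = None
    if bouts is not None:
        n_bouts = len(bouts)
        if n_bouts:
            prox_share = sum(b.is_proximity_only for b in bouts) / n_bouts
        else:
            prox_share = float("nan")
    return FrequencyTable(counts, prop, prox_share)


def build_ethogram(markov: MarkovModel, residuals: ResidualTable,
                   frequency: FrequencyTable) -> EthogramModel:
    category = classify_behaviors(markov, residuals)
    model = EthogramModel(markov, residuals, frequency, category)
    # proportions over initiated physical behaviors must be a distribution
    s = sum(v for v in frequency.proportion_physical.values() if v == v)
    if s and abs(s - 1.0) > 1e-9:
        raise ValueError("physical-behavior proportions do not sum to 1")
    return model


def to_graph(model: EthogramModel) -> nx.DiGraph:
    """Directed graph with node size/category and edge probability/significance."""
    g = nx.DiGraph()
    labels = list(model.markov.row_labels) + ["end"]
    for b in dict.fromkeys(labels):
        cat = model.category.get(b, "nonaggressive")
        g.add_node(b, size=model.frequency.counts.get(b, 0), category=cat,
                   color=_CATEGORY_COLOR.get(cat, "blue"))
    for i, src in enumerate(model.markov.row_labels):
        if not model.markov.defined[i]:
            continue
        for j, tgt in enumerate(model.markov.col_labels):
            p = model.markov.prob[i, j]
            if not p > 0:
                continue
            sig = bool(model.residuals.significant[i, j])
            g.add_edge(src, tgt, weight=float(p), significant=sig,
                       label=(f"{p:.2f}" if sig else ""))
    return g


def export_ethogram_graph(model: EthogramModel, path_base) -> Tuple[Path, Path]:
    """Write the ethogram as DOT and GraphML files; returns both paths."""
    g = to_graph(model)
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    dot_path = base.with_suffix(".dot")
    graphml_path = base.with_suffix(".graphml")

    lines = ["digraph ethogram {"]
    for n, d in g.nodes(data=True):
        lines.append(f'  "{n}" [width={d["size"]}, category="{d["category"]}", '
                     f'color="{d["color"]}"];')
    for u, v, d in g.edges(data=True):
        style = "solid" if d["significant"] else "dashed"
        color = "black" if d["significant"] else "gray"
        lines.append(f'  "{u}" -> "{v}" [penwidth={d["weight"]:.4f}, '
                     f'label="{d["label"]}", color="{color}", style={style}];')
    lines.append("}")
    dot_path.write_text("\n".join(lines) + "\n")

    nx.write_graphml(g, graphml_path)
    return dot_path, graphml_path


__all__ = [
    "CATEGORIES", "FrequencyTable", "EthogramModel", "classify_behaviors",
    "behavior_frequencies", "build_ethogram", "to_graph", "export_ethogram_graph",
]
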