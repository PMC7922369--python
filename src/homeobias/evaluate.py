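"""Scoring pipeline output against planted ground truth.

Used to benchmark the analysis on synthetic bundles: how many planted
components were recovered with the right class, how many planted
sub-/neo-functionalization labels the bias classifier got right, and
whether family membership and subgroup assignment are exact.
"""

from __future__ import annotations

import pandas as pd

from .bias import BiasCall
from .components import HomeologComponent
from .synthetic import GroundTruth

EXPECTED_STATUS = {
    ("sub", 1): "subfunctionalization_up",
    ("sub", -1): "subfunctionalization_down",
    ("neo", 1): "neofunctionalization",
    ("neo", -1): "neofunctionalization",
    ("null", 0): "unchanged",
}


def expected_bias_status(label: str, direction: int) -> str:
    return EXPECTED_STATUS[(label, direction)]


def score_family_recovery(truth: GroundTruth, member_ids: set[str]) -> dict[str, float]:
    """Sensitivity/specificity of family identification."""
    fam = set(truth.genes.index[truth.genes["is_family"]])
    non = set(truth.genes.index) - fam
    tp = len(fam & member_ids)
    tn = len(non - member_ids)
    return {
        "sensitivity": tp / len(fam) if fam else 1.0,
        "specificity": tn / len(non) if non else 1.0,
    }


def score_component_recovery(
    truth: GroundTruth, components: list[HomeologComponent]
) -> float:
    """Fraction of planted components recovered with identical member
    set AND the planted class."""
    predicted = {
        frozenset(c.members): c.component_class for c in components
    }
    truth_members = truth.component_members()
    ok = 0
    for cid, members in truth_members.items():
        cls = truth.components.loc[cid, "class"]
        if predicted.get(frozenset(members)) == cls:
            ok += 1
    return ok / len(truth_members)


def score_subgroup_recovery(
    truth: GroundTruth, assignment: dict
) -> float:
    """Fraction of family genes with the planted phylo group + subgroup."""
    fam = truth.genes[truth.genes["is_family"]]
    ok = 0
    for gid, row in fam.iterrows():
        call = assignment.get(gid)
        if (
            call is not None
            and call.phylo_group == row["phylo_group"]
            and call.subgroup == row["subgroup"]
        ):
            ok += 1
    return ok / len(fam)


def score_bias_recovery(
    truth: GroundTruth, calls: list[BiasCall],
    components: list[HomeologComponent],
    labels: tuple[str, ...] = ("sub", "neo", "null"),
) -> float:
    """Fraction of planted components (restricted to ``labels``) whose
    bias status matches the planted expectation."""
    comp_members = {c.id: frozenset(c.members) for c in components}
    status_by_members = {
        comp_members[c.component_id]: c.status for c in calls
    }
    truth_members = truth.component_members()
    ok = tot = 0
    for cid, members in truth_members.items():
        label = truth.components.loc[cid, "bias_label"]
        if label not in labels:
            continue
        direction = int(truth.components.loc[cid, "bias_direction"])
        tot += 1
        if status_by_members.get(frozenset(members)) == expected_bias_status(label, direction):
            ok += 1
    return ok / tot if tot else 1.0


def bias_calls_from_tables(components_tsv, bias_tsv) -> tuple[list, list]:
    """Rehydrate components + bias calls from pipeline output tables."""
    comp = pd.read_csv(components_tsv, sep="\t")
    bias = pd.read_csv(bias_tsv, sep="\t")
    comps = [
        HomeologComponent(
            id=str(r.component_id),
            members=str(r.members).split(","),
            component_class=str(getattr(r, "_1")),
        )
        for r in comp.itertuples(index=False)
    ]
    calls = [
        BiasCall(component_id=str(r.component_id), status=str(r.status), member_calls={})
        for r in bias.itertuples(index=False)
    ]
    return comps, calls
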