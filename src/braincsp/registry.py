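"""Reaction registry: canonical ordering of all unidirectional rates.

The metabolic model comprises 65 numbered reactions and currents, of
which numbers 42-53 belong to the electrophysiological part of the
original model and do not appear in the brain-activation scenario.  The
remaining 53 numbered reactions, with every reversible pair split into
non-negative forward/backward parts, give the 67 unidirectional labels
used for stoichiometry columns, rate vectors, per-reaction Jacobians and
all diagnostic reports.  Labels are sorted by reaction number, forward
before backward.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Reaction:
    label: str          # e.g. "5f", "27b", "63"
    number: int         # the published reaction number
    direction: str      # "f", "b" or "" for unidirectional
    name: str           # human-readable description
    compartment: str    # n, g, e, c, v (vascular) or a transfer tag like "e->n"


_PAIRS: dict[int, tuple[str, str]] = {
    5: ("glucose transport e->n", "e->n"),
    6: ("glucose transport e->g", "e->g"),
    7: ("glucose transport c->g", "c->g"),
    8: ("glucose transport c->e", "c->e"),
    15: ("lactate dehydrogenase (neuron)", "n"),
    16: ("lactate dehydrogenase (astrocyte)", "g"),
    17: ("lactate transport n->e", "n->e"),
    18: ("lactate transport g->e", "g->e"),
    19: ("lactate transport g->c", "g->c"),
    20: ("lactate transport e->c", "e->c"),
    27: ("creatine kinase (neuron)", "n"),
    28: ("creatine kinase (astrocyte)", "g"),
    64: ("creatine kinase ATP yield (neuron)", "n"),
    65: ("creatine kinase ATP yield (astrocyte)", "g"),
}

_SINGLES: dict[int, tuple[str, str]] = {
    1: ("sodium leak (neuron)", "n"),
    2: ("sodium leak (astrocyte)", "g"),
    3: ("Na,K-ATPase sodium extrusion (neuron)", "n"),
    4: ("Na,K-ATPase sodium extrusion (astrocyte)", "g"),
    9: ("hexokinase-phosphofructokinase (neuron)", "n"),
    10: ("hexokinase-phosphofructokinase (astrocyte)", "g"),
    11: ("phosphoglycerate kinase (neuron)", "n"),
    12: ("phosphoglycerate kinase (astrocyte)", "g"),
    13: ("pyruvate kinase (neuron)", "n"),
    14: ("pyruvate kinase (astrocyte)", "g"),
    21: ("TCA cycle input (neuron)", "n"),
    22: ("electron transport chain (neuron)", "n"),
    23: ("TCA cycle input (astrocyte)", "g"),
    24: ("electron transport chain (astrocyte)", "g"),
    25: ("NADH shuttle (neuron)", "n"),
    26: ("NADH shuttle (astrocyte)", "g"),
    29: ("oxygen exchange c->n", "c->n"),
    30: ("oxygen exchange c->g", "c->g"),
    31: ("capillary oxygen flow", "c"),
    32: ("capillary glucose flow", "c"),
    33: ("capillary lactate flow", "c"),
    34: ("housekeeping ATPase offset (neuron)", "n"),
    35: ("housekeeping ATPase offset (astrocyte)", "g"),
    36: ("astrocytic Na,K-ATPase pump offset", "g"),
    37: ("venous volume balance", "v"),
    38: ("deoxyhemoglobin inflow", "v"),
    39: ("deoxyhemoglobin washout", "v"),
    40: ("presynaptic sodium stimulation (neuron)", "n"),
    41: ("presynaptic sodium stimulation (astrocyte, EAAT)", "g"),
    54: ("ATP investment by HK-PFK (neuron)", "n"),
    55: ("ATP investment by HK-PFK (astrocyte)", "g"),
    56: ("ATP yield of PGK (neuron)", "n"),
    57: ("ATP yield of PGK (astrocyte)", "g"),
    58: ("ATP yield of PK (neuron)", "n"),
    59: ("ATP yield of PK (astrocyte)", "g"),
    60: ("ATP consumption by Na,K-ATPase (neuron)", "n"),
    61: ("ATP consumption by Na,K-ATPase (astrocyte)", "g"),
    62: ("ATP yield of electron transport chain (neuron)", "n"),
    63: ("ATP yield of electron transport chain (astrocyte)", "g"),
}


def _build() -> list[Reaction]:
    out: list[Reaction] = []
    for num in sorted(set(_PAIRS) | set(_SINGLES)):
        if num in _PAIRS:
            name, comp = _PAIRS[num]
            out.append(Reaction(f"{num}f", num, "f", name + " (forward)", comp))
            out.append(Reaction(f"{num}b", num, "b", name + " (backward)", comp))
        else:
            name, comp = _SINGLES[num]
            out.append(Reaction(str(num), num, "", name, comp))
    return out


#: Ordered list of all unidirectional reactions.
REACTIONS: tuple[Reaction, ...] = tuple(_build())

#: Ordered labels, the public contract for stoichiometry columns.
LABELS: tuple[str, ...] = tuple(r.label for r in REACTIONS)

N_REACTIONS = len(LABELS)

LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}


def reaction(label: str) -> Reaction:
    try:
        return REACTIONS[LABEL_INDEX[label]]
    except KeyError:
        raise KeyError(f"unknown reaction label {label!r}") from None


def reversible_partner(label: str) -> str | None:
    """The other direction of a reversible pair, or None."""
    r = reaction(label)
    if r.direction == "f":
        return f"{r.number}b"
    if r.direction == "b":
        return f"{r.number}f"
    return None
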