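"""The nearest-carbon ± 2 regiospecificity rule with oxygen-channel gating.

The catalytic iron abstracts a hydrogen from the substrate carbon nearest to
it (Cn); molecular oxygen then attacks two carbons away, at n−2 or n+2.
Which side is taken is decided by where O2 can reach the substrate: with the
channel gate open (glycine) the attack happens on the candidate toward the
pocket entrance, with the gate closed (alanine) O2 is driven deeper and the
attack happens on the candidate toward the pocket bottom.  Which chain index
lies on which side depends on the substrate orientation: with the carboxyl
head external, lower indices are toward the entrance; with the head buried,
the mapping flips.

The resulting enzyme label is "LOX{k}" with k the oxidized carbon, numbered
from the carboxyl carbon (C1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pocket import (
    GateState,
    LigandChain,
    Orientation,
    PocketFrame,
    nearest_carbon,
)

__all__ = ["RegiochemistryCall", "call_lox_type_categorical", "call_lox_type_geometric"]


@dataclass(frozen=True)
class RegiochemistryCall:
    """One LOX-type call with its rationale.

    ``candidates`` are the in-range members of {n−2, n+2}; ``oxidation`` is
    the selected carbon; flags record edge conditions (a distance tie at the
    iron, a chosen carbon not flanking a recorded double bond, or a
    single-candidate fallback at a chain end).
    """

    nearest: int
    candidates: tuple[int, ...]
    oxidation: int
    gate: GateState
    orientation: Orientation
    flags: frozenset[str] = frozenset()
    rationale: dict[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if abs(self.oxidation - self.nearest) != 2:
            raise ValueError("oxidation carbon must be two positions from nearest")

    @property
    def lox_type(self) -> str:
        return f"LOX{self.oxidation}"


def _candidates(n: int, chain_length: int) -> tuple[int, ...]:
    return tuple(k for k in (n - 2, n + 2) if 1 <= k <= chain_length)


def call_lox_type_categorical(
    n: int,
    chain_length: int,
    orientation: Orientation,
    gate: GateState,
    tie_at_iron: bool = False,
) -> RegiochemistryCall:
    """LOX-type from the categorical rule (no coordinates needed).

    The candidates n−2 and n+2 are assigned to the entrance side and the
    deep side of the pocket according to ``orientation``; an open gate
    selects the entrance-side candidate and a closed gate the deep-side one.
    If the selected candidate falls outside the chain the other candidate is
    used and ``single_candidate`` is flagged.
    """
    if not 1 <= n <= chain_length:
        raise ValueError(f"nearest carbon {n} outside chain [1, {chain_length}]")
    cands = _candidates(n, chain_length)
    if not cands:
        raise ValueError(
            f"no oxidation candidate in range for nearest carbon {n} on a "
            f"{chain_length}-carbon chain"
        )
    if orientation is Orientation.HEAD_EXTERNAL:
        external_side, deep_side = n - 2, n + 2
    else:
        external_side, deep_side = n + 2, n - 2
    chosen = external_side if gate.is_open else deep_side
    flags = set()
    if tie_at_iron:
        flags.add("tie_at_iron")
    if chosen not in cands:
        chosen = cands[0]
        flags.add("single_candidate")
    elif len(cands) == 1:
        flags.add("single_candidate")
    return RegiochemistryCall(
        nearest=n,
        candidates=cands,
        oxidation=chosen,
        gate=gate,
        orientation=orientation,
        flags=frozenset(flags),
        rationale={
            "external_side": external_side,
            "deep_side": deep_side,
            "gate_open": gate.is_open,
        },
    )


def call_lox_type_geometric(
    chain: LigandChain,
    frame: PocketFrame,
    gate: GateState,
    fe_xyz=None,
) -> RegiochemistryCall:
    """LOX-type from pose geometry.

    The nearest-to-iron carbon gives n; the O2 delivery point is the channel
    mouth when the gate is open, else the pocket bottom; among the in-range
    candidates {n−2, n+2} the carbon closest to the delivery point is
    oxidized.  ``candidate_not_at_double_bond`` is flagged when the chosen
    carbon does not flank a recorded double bond.
    """
    fe = np.asarray(frame.fe if fe_xyz is None else fe_xyz)
    n, dist, tie = nearest_carbon(chain, fe)
    cands = _candidates(n, chain.n)
    if not cands:
        raise ValueError(
            f"no oxidation candidate in range for nearest carbon {n} on a "
            f"{chain.n}-carbon chain"
        )
    from .pocket import head_orientation  # local import avoids cycle at module load

    orientation = head_orientation(chain, frame)
    delivery = np.asarray(frame.mouth if gate.is_open else frame.bottom)
    cand_dist = {k: float(np.linalg.norm(chain.carbon(k) - delivery)) for k in cands}
    chosen = min(cands, key=lambda k: (cand_dist[k], k))
    flags = set()
    if tie:
        flags.add("tie_at_iron")
    if len(cands) == 1:
        flags.add("single_candidate")
    # a double bond at index i spans carbons i and i+1
    at_double = any(chosen in (i, i + 1) for i in chain.double_bonds)
    if chain.double_bonds and not at_double:
        flags.add("candidate_not_at_double_bond")
    return RegiochemistryCall(
        nearest=n,
        candidates=cands,
        oxidation=chosen,
        gate=gate,
        orientation=orientation,
        flags=frozenset(flags),
        rationale={
            "fe_distance": round(dist, 3),
            "candidate_delivery_distances": {
                str(k): round(v, 3) for k, v in cand_dist.items()
            },
            "delivery_point": "mouth" if gate.is_open else "bottom",
        },
    )
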