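"""The 17-group architecture of the columnar model.

A *group* is a (layer, cell type) pair. Layers 2/3, 4, 5 and 6 each contain
an excitatory population (E) and three inhibitory interneuron classes
(PV, SST, VIP); layer 1 contains only VIP cells, giving 17 groups in total.

The canonical group order used for all matrix I/O and for assigning neuron
id ranges is: VIP1 first, then per layer (2/3, 4, 5, 6) the types in the
order E, PV, SST, VIP.
"""

from __future__ import annotations

from dataclasses import dataclass

LAYERS = ("L1", "L2/3", "L4", "L5", "L6")
FULL_LAYERS = ("L2/3", "L4", "L5", "L6")
CELL_TYPES = ("E", "PV", "SST", "VIP")

#: suffix used in group labels, e.g. "E2/3", "PV4", "VIP1"
_LAYER_SUFFIX = {"L1": "1", "L2/3": "2/3", "L4": "4", "L5": "5", "L6": "6"}
_SUFFIX_LAYER = {v: k for k, v in _LAYER_SUFFIX.items()}


@dataclass(frozen=True, order=True)
class GroupId:
    """Identifier of one cell group: a layer and a cell type.

    Layer 1 admits only VIP cells; the four full layers admit all four
    types. Exactly 17 combinations are valid.
    """

    layer: str
    cell_type: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if self.layer == "L1" and self.cell_type != "VIP":
            raise ValueError("layer 1 contains only VIP cells")

    @property
    def label(self) -> str:
        """Short label, e.g. ``E2/3`` or ``VIP1``."""
        return f"{self.cell_type}{_LAYER_SUFFIX[self.layer]}"

    @classmethod
    def from_label(cls, label: str) -> "GroupId":
        for t in sorted(CELL_TYPES, key=len, reverse=True):
            if label.startswith(t):
                suffix = label[len(t):]
                if suffix in _SUFFIX_LAYER:
                    return cls(_SUFFIX_LAYER[suffix], t)
        raise ValueError(f"unrecognized group label {label!r}")

    @property
    def is_excitatory(self) -> bool:
        return self.cell_type == "E"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def canonical_groups() -> tuple[GroupId, ...]:
    """The 17 groups in canonical order (VIP1, then E/PV/SST/VIP per layer)."""
    groups = [GroupId("L1", "VIP")]
    for layer in FULL_LAYERS:
        for t in CELL_TYPES:
            groups.append(GroupId(layer, t))
    return tuple(groups)


GROUPS: tuple[GroupId, ...] = canonical_groups()
GROUP_INDEX: dict[GroupId, int] = {g: i for i, g in enumerate(GROUPS)}
GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in GROUPS)
N_GROUPS = len(GROUPS)
assert N_GROUPS == 17
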