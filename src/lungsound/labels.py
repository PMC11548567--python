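"""The four respiratory-cycle classes and the crackle/wheeze flag mapping."""

from __future__ import annotations

from enum import IntEnum


class Label(IntEnum):
    """Class of one respiratory cycle.

    The integer values double as row/column indices in confusion matrices and
    as the dense-label encoding of :class:`~lungsound.preprocess.DatasetMatrix`.
    """

    NORMAL = 0
    CRACKLE = 1
    WHEEZE = 2
    BOTH = 3


CLASS_NAMES: tuple[str, ...] = tuple(lbl.name.lower() for lbl in Label)

N_CLASSES = len(Label)


def label_of(crackle: bool | int, wheeze: bool | int) -> Label:
    """Map a (crackle, wheeze) annotation flag pair to its class.

    The mapping is a bijection between the four flag pairs and the four
    classes: (0,0) -> normal, (1,0) -> crackle, (0,1) -> wheeze, (1,1) -> both.
    """
    c, w = bool(crackle), bool(wheeze)
    if c and w:
        return Label.BOTH
    if c:
        return Label.CRACKLE
    if w:
        return Label.WHEEZE
    return Label.NORMAL


def flags_of(label: Label) -> tuple[int, int]:
    """Inverse of :func:`label_of`: class -> (crackle, wheeze) flags."""
    label = Label(label)
    return (
        int(label in (Label.CRACKLE, Label.BOTH)),
        int(label in (Label.WHEEZE, Label.BOTH)),
    )
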