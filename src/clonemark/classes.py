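"""Junction-class taxonomy for IG/TR rearrangements.

A *junction class* names a rearrangement type by the roles and loci of the
two joined germline elements: complete V-J joints (with any D contribution
absorbed into the junction), incomplete D-J and V-D intermediates, and the
non-coding "other" joints (kappa-deleting element rearrangements and the
rare D-D joints of TRB/TRD).  Exactly 22 classes over the seven antigen
receptor loci are recognized; cross-locus TRA/TRD hybrid joints form their
own locus group (``TRA+D``).
"""

from __future__ import annotations

from dataclasses import dataclass

LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG", "TRD")

# segment roles
V = "V"
D = "D"
J = "J"
KDE = "KDE"
INTRON_RSS = "INTRON_RSS"
SEGMENT_TYPES = (V, D, J, KDE, INTRON_RSS)

# categories (functional grouping of classes)
COMPLETE_VJ = "complete_VJ"
INCOMPLETE_DJ = "incomplete_DJ"
INCOMPLETE_VD = "incomplete_VD"
OTHER = "other"
CATEGORIES = (COMPLETE_VJ, INCOMPLETE_DJ, INCOMPLETE_VD, OTHER)


@dataclass(frozen=True)
class JunctionClass:
    """One of the 22 recognized rearrangement types."""

    label: str
    locus_group: str
    category: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Registry of all junction classes, in canonical report order
#: (IGH, IGK, IGL, TRA, TRA+D, TRB, TRD, TRG).
JUNCTION_CLASSES: tuple[JunctionClass, ...] = (
    JunctionClass("Vh-(Dh)-Jh", "IGH", COMPLETE_VJ),
    JunctionClass("Dh-Jh", "IGH", INCOMPLETE_DJ),
    JunctionClass("Vk-Jk", "IGK", COMPLETE_VJ),
    JunctionClass("Vk-Kde", "IGK", OTHER),
    JunctionClass("intron-Kde", "IGK", OTHER),
    JunctionClass("Vl-Jl", "IGL", COMPLETE_VJ),
    JunctionClass("Va-Ja", "TRA", COMPLETE_VJ),
    JunctionClass("Va-Jd", "TRA+D", COMPLETE_VJ),
    JunctionClass("Vd-(Dd)-Ja", "TRA+D", COMPLETE_VJ),
    JunctionClass("Dd-Ja", "TRA+D", INCOMPLETE_DJ),
    JunctionClass("Va-Dd", "TRA+D", INCOMPLETE_VD),
    JunctionClass("Vb-(Db)-Jb", "TRB", COMPLETE_VJ),
    JunctionClass("Db-Jb", "TRB", INCOMPLETE_DJ),
    JunctionClass("Vb-Db", "TRB", INCOMPLETE_VD),
    JunctionClass("Db-Db", "TRB", OTHER),
    JunctionClass("Vd-(Dd)-Jd", "TRD", COMPLETE_VJ),
    JunctionClass("Dd2-Jd1", "TRD", INCOMPLETE_DJ),
    JunctionClass("Dd3-Jd", "TRD", INCOMPLETE_DJ),
    JunctionClass("Vd-Dd3", "TRD", INCOMPLETE_VD),
    JunctionClass("Dd2-Dd3", "TRD", OTHER),
    JunctionClass("Dd3-Dd2", "TRD", OTHER),
    JunctionClass("Vg-Jg", "TRG", COMPLETE_VJ),
)

CLASS_BY_LABEL: dict[str, JunctionClass] = {c.label: c for c in JUNCTION_CLASSES}

#: Classes whose 5' element carries a reading-frame anchor (V-element joints).
CODING_5PRIME_CATEGORIES = (COMPLETE_VJ,)


class UnclassifiablePairError(ValueError):
    """Raised when a segment pair matches none of the 22 junction classes."""

    def __init__(self, five, three):
        self.five = five
        self.three = three
        super().__init__(
            f"segment pair ({five.name}[{five.locus}/{five.segment_type}], "
            f"{three.name}[{three.locus}/{three.segment_type}]) matches no "
            "junction class"
        )


def _trd_d_number(name: str) -> int | None:
    up = name.upper()
    if up.startswith("TRDD2"):
        return 2
    if up.startswith("TRDD3"):
        return 3
    return None


def _is_trd_j1(name: str) -> bool:
    return name.upper().startswith("TRDJ1")


def classify_junction_class(five, three) -> JunctionClass:
    """Assign the junction class for a (5' segment, 3' segment) pair.

    Dispatch is on locus and segment type, with the TRD D-gene-specific
    classes (Dd2/Dd3) resolved by gene name.  Raises
    :class:`UnclassifiablePairError` for pairs outside the taxonomy
    (e.g. an IGH V joined to a TRB J).
    """
    key = (five.locus, five.segment_type, three.locus, three.segment_type)
    simple = {
        ("IGH", V, "IGH", J): "Vh-(Dh)-Jh",
        ("IGH", D, "IGH", J): "Dh-Jh",
        ("IGK", V, "IGK", J): "Vk-Jk",
        ("IGK", V, "IGK", KDE): "Vk-Kde",
        ("IGK", INTRON_RSS, "IGK", KDE): "intron-Kde",
        ("IGL", V, "IGL", J): "Vl-Jl",
        ("TRA", V, "TRA", J): "Va-Ja",
        ("TRA", V, "TRD", J): "Va-Jd",
        ("TRD", V, "TRA", J): "Vd-(Dd)-Ja",
        ("TRD", D, "TRA", J): "Dd-Ja",
        ("TRA", V, "TRD", D): "Va-Dd",
        ("TRB", V, "TRB", J): "Vb-(Db)-Jb",
        ("TRB", D, "TRB", J): "Db-Jb",
        ("TRB", V, "TRB", D): "Vb-Db",
        ("TRB", D, "TRB", D): "Db-Db",
        ("TRD", V, "TRD", J): "Vd-(Dd)-Jd",
        ("TRG", V, "TRG", J): "Vg-Jg",
    }
    label = simple.get(key)
    if key == ("TRD", D, "TRD", J):
        dn = _trd_d_number(five.name)
        if dn == 2 and _is_trd_j1(three.name):
            label = "Dd2-Jd1"
        elif dn == 3:
            label = "Dd3-Jd"
    elif key == ("TRD", V, "TRD", D):
        if _trd_d_number(three.name) == 3:
            label = "Vd-Dd3"
    elif key == ("TRD", D, "TRD", D):
        pair = (_trd_d_number(five.name), _trd_d_number(three.name))
        if pair == (2, 3):
            label = "Dd2-Dd3"
        elif pair == (3, 2):
            label = "Dd3-Dd2"
    if label is None:
        raise UnclassifiablePairError(five, three)
    return CLASS_BY_LABEL[label]
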