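"""Odorant panel: 104 human-derived odorants in 11 chemical classes.

The panel mirrors the composition of the screened human-odorant set
(carboxylic acids are the largest group with 21 members; aldehydes number
11; amines 3) and supplies the class vocabulary used for bias statistics.
Odorants named in the source recordings (nonanal, sulcatone, the amines,
the chlorinated alkanes, ...) appear under those names; the remainder of
each class is filled with representative human skin-emanation volatiles.
"""

from __future__ import annotations

SENSILLA = ("Da", "Db", "Dg", "C", "E1", "E2")
"""ASCII tokens for the six sensillum types, in canonical column order."""

SENSILLUM_DISPLAY = {
    "Da": "Dα",
    "Db": "Dβ",
    "Dg": "Dγ",
    "C": "C",
    "E1": "E1",
    "E2": "E2",
}

_CLASS_MEMBERS = {
    "aldehyde": [
        "propanal", "butanal", "pentanal", "hexanal", "heptanal", "octanal",
        "nonanal", "decanal", "undecanal", "dodecanal", "benzaldehyde",
    ],
    "amine": ["ammonia", "propylamine", "butylamine"],
    "carboxylic_acid": [
        "acetic acid", "propionic acid", "butyric acid", "valeric acid",
        "2-methylvaleric acid", "hexanoic acid", "heptanoic acid",
        "octanoic acid", "nonanoic acid", "decanoic acid", "undecanoic acid",
        "lauric acid", "tridecanoic acid", "myristic acid",
        "pentadecanoic acid", "pimelic acid", "adipic acid", "acrylic acid",
        "benzoic acid", "4-hydroxybenzoic acid", "oleic acid",
    ],
    "alcohol": [
        "cis-2-hexen-1-ol", "trans-2-hexen-1-ol", "1-hexanol", "1-heptanol",
        "1-octanol", "1-octen-3-ol", "2-ethyl-1-hexanol", "benzyl alcohol",
        "geraniol", "linalool",
    ],
    "ketone": [
        "acetone", "2-butanone", "2-pentanone", "3-pentanone", "2-hexanone",
        "2-heptanone", "2-decanone", "sulcatone",
    ],
    "halide": [
        "1-chlorohexane", "1-chloroheptane", "1-chlorooctane",
        "1-chlorodecane", "1-chlorododecane", "1-chlorotetradecane",
        "1-chlorohexadecane", "lauroyl chloride",
    ],
    "aromatic": [
        "toluene", "ethylbenzene", "propylbenzene", "styrene", "phenol",
        "p-cresol", "xylene", "naphthalene", "acetophenone", "benzonitrile",
    ],
    "aliphatic": [
        "decane", "dodecane", "tetradecane", "pentadecane", "hexadecane",
        "octadecane", "1-dodecene", "1-tetradecene", "1-hexadecene",
        "squalene",
    ],
    "heterocyclic": [
        "thiazolidine", "1-methylpiperazine", "methylpyrazine", "pyridine",
        "pyrrole", "piperidine", "indole", "3-methylindole", "furan",
        "thiophene",
    ],
    "ester": [
        "methyl tridecanoate", "ethyl acetate", "ethyl butyrate",
        "ethyl hexanoate", "methyl octanoate", "isoamyl acetate",
        "methyl salicylate",
    ],
    "amide": [
        "urea", "ethylurea", "formamide", "acetamide", "propanamide",
        "butyramide",
    ],
}

CLASSES = tuple(_CLASS_MEMBERS)
"""The 11-class chemical vocabulary."""

PANEL = {od: cls for cls, members in _CLASS_MEMBERS.items() for od in members}
"""Mapping odorant id -> chemical class (104 entries)."""

assert len(PANEL) == 104, "panel must contain 104 distinct odorants"


def class_members(cls: str) -> list[str]:
    """Return the odorants belonging to one chemical class."""
    return list(_CLASS_MEMBERS[cls])
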