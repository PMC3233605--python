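"""Drug dictionary and the three-level psychotropic hierarchy.

Level 1 groups drugs into *antipsychotic* vs *mood_stabiliser*; Level 2 into
the classes FGA, SGA, anticonvulsant and lithium; Level 3 is the individual
generic drug.  The dictionary maps raw prescription drug codes to generic
names and classes; the Level 1 group is derived from the class, so the
hierarchy is a partition by construction.  Codes absent from the dictionary
classify to an explicit ``unclassified`` marker and are excluded from every
analysis (but counted, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

UNCLASSIFIED = "unclassified"

ANTIPSYCHOTIC = "antipsychotic"
MOOD_STABILISER = "mood_stabiliser"
LEVEL1_GROUPS = (ANTIPSYCHOTIC, MOOD_STABILISER)

LEVEL2_TO_LEVEL1 = {
    "FGA": ANTIPSYCHOTIC,
    "SGA": ANTIPSYCHOTIC,
    "anticonvulsant": MOOD_STABILISER,
    "lithium": MOOD_STABILISER,
}
ANTICONVULSANT_GENERICS = {"carbamazepine", "lamotrigine", "valproate"}

DICTIONARY_COLUMNS = ["drug_code", "generic_name", "level2_class"]


@dataclass(frozen=True)
class HierarchyUnit:
    """A node of the drug hierarchy: (level, label)."""

    level: int
    label: str

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise ValueError(f"hierarchy level must be 1, 2 or 3, got {self.level}")


class DrugDictionary:
    """Lookup from drug codes to (generic_name, level2_class, level1_group)."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in DICTIONARY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"drug dictionary missing column(s): {', '.join(missing)}")
        if frame["drug_code"].duplicated().any():
            dup = frame.loc[frame["drug_code"].duplicated(), "drug_code"].iloc[0]
            raise ValueError(f"duplicate drug code in dictionary: {dup!r}")
        bad_class = ~frame["level2_class"].isin(LEVEL2_TO_LEVEL1)
        if bad_class.any():
            raise ValueError(
                f"unknown level2_class {frame.loc[bad_class, 'level2_class'].iloc[0]!r}"
            )
        anticon = frame["level2_class"] == "anticonvulsant"
        bad_ac = anticon & ~frame["generic_name"].isin(ANTICONVULSANT_GENERICS)
        if bad_ac.any():
            raise ValueError(
                "anticonvulsant generic must be carbamazepine, lamotrigine or "
                f"valproate; got {frame.loc[bad_ac, 'generic_name'].iloc[0]!r}"
            )
        frame["level1_group"] = frame["level2_class"].map(LEVEL2_TO_LEVEL1)
        self.frame = frame[DICTIONARY_COLUMNS + ["level1_group"]].reset_index(drop=True)
        self._by_code = {
            r.drug_code: (r.generic_name, r.level2_class, r.level1_group)
            for r in self.frame.itertuples()
        }

    @classmethod
    def from_csv(cls, path) -> "DrugDictionary":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"drug dictionary not found: {path}")
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.frame[DICTIONARY_COLUMNS].to_csv(path, index=False)

    def classify(self, drug_code: str) -> tuple[str, str, str]:
        """Return (generic_name, level2_class, level1_group); unknown codes
        map to the ``unclassified`` marker in every position."""
        return self._by_code.get(drug_code, (UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED))

    def classify_frame(self, prescriptions: pd.DataFrame) -> pd.DataFrame:
        """Annotate a prescriptions frame with generic/class/group columns.

        Unknown codes are kept in the output with the ``unclassified`` marker
        so callers can count them before excluding them.
        """
        out = prescriptions.merge(self.frame, on="drug_code", how="left")
        for col in ("generic_name", "level2_class", "level1_group"):
            out[col] = out[col].fillna(UNCLASSIFIED)
        return out

    def units(self) -> list[HierarchyUnit]:
        """Every hierarchy unit present in the dictionary, L1 then L2 then L3."""
        out = [HierarchyUnit(1, g) for g in LEVEL1_GROUPS
               if g in set(self.frame["level1_group"])]
        out += [HierarchyUnit(2, c) for c in LEVEL2_TO_LEVEL1
                if c in set(self.frame["level2_class"])]
        out += [HierarchyUnit(3, g) for g in sorted(self.frame["generic_name"].unique())]
        return out

    def generics(self) -> list[str]:
        return sorted(self.frame["generic_name"].unique())

    def __len__(self) -> int:
        return len(self.frame)


def classify_drug(drug_code: str, dictionary: DrugDictionary) -> tuple[str, str, str]:
    """Functional form of :meth:`DrugDictionary.classify`."""
    return dictionary.classify(drug_code)
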