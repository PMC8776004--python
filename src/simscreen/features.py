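"""Pharmacophoric feature typing shared by the 2D-pharmacophore and
reduced-graph fingerprints.

Feature rules live in ``data/pharmacophore_features.yaml`` as SMARTS patterns
grouped into six classes (donor, acceptor, cation, anion, aromatic,
hydrophobic).  A feature *point* is the atom set of one SMARTS match;
overlapping matches of the same class are merged so e.g. the two SMARTS hits
on a carboxylate produce a single anion point.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml
from rdkit import Chem

FEATURE_CLASSES = ("donor", "acceptor", "cation", "anion", "aromatic", "hydrophobic")


@dataclass(frozen=True)
class FeaturePoint:
    """One pharmacophoric point: a feature class and the atoms carrying it."""

    kind: str
    atoms: frozenset[int]


@lru_cache(maxsize=1)
def _compiled_rules() -> dict[str, list[Chem.Mol]]:
    text = (
        resources.files("simscreen").joinpath("data/pharmacophore_features.yaml")
    ).read_text()
    raw = yaml.safe_load(text)
    rules: dict[str, list[Chem.Mol]] = {}
    for kind, patterns in raw["features"].items():
        compiled = []
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for {kind}: {smarts}")
            compiled.append(patt)
        rules[kind] = compiled
    return rules


def assign_features(mol: Chem.Mol) -> list[FeaturePoint]:
    """Type every pharmacophoric point in the molecule.

    Matches of the same class whose atom sets overlap are merged into one
    point.  The result is sorted (class, atom indices) for determinism; the
    atom sets themselves are order-invariant.
    """
    points: list[FeaturePoint] = []
    for kind in FEATURE_CLASSES:
        matches: list[set[int]] = []
        for patt in _compiled_rules()[kind]:
            for match in mol.GetSubstructMatches(patt, uniquify=True):
                matches.append(set(match))
        merged: list[set[int]] = []
        for m in matches:
            absorbed = False
            for existing in merged:
                if existing & m:
                    existing |= m
                    absorbed = True
                    break
            if not absorbed:
                merged.append(m)
        # merging can chain: repeat until stable
        changed = True
        while changed:
            changed = False
            for i in range(len(merged)):
                for j in range(i + 1, len(merged)):
                    if merged[i] & merged[j]:
                        merged[i] |= merged.pop(j)
                        changed = True
                        break
                if changed:
                    break
        points.extend(FeaturePoint(kind, frozenset(m)) for m in merged)
    return sorted(points, key=lambda p: (p.kind, sorted(p.atoms)))
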