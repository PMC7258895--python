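"""Bilateral motor-network topology and the factorial 4x3 model space.

The network has eight regions, four per hemisphere, named relative to the
moved limb: contralateral primary motor cortex (cM1), premotor cortex (cPM),
supplementary motor area (cSMA) and primary somatosensory cortex (cS1), and
their ipsilateral counterparts (iM1, iPM, iSMA, iS1). The base topology fully
connects {M1, PM, SMA} within each hemisphere (all six directed edges per
hemisphere) and joins the hemispheres through reciprocal M1-M1 and SMA-SMA
edges; S1 carries no edges in the base model.

Candidate models vary along two factors:

* an S1-connection family (1..4) adding efferent S1 edges in both
  hemispheres — none, S1->M1, S1->PM, or both; S1 never receives edges;
* a stimulus-target family (1..3) choosing which contralateral regions the
  external input drives — {PM, S1}, {PM, S1, M1}, or {S1, M1}.

The 12 models are numbered column-major over the factors,
``id = 3*(s1_family-1) + stim_family``, the unique scheme under which model 11
is the (S1->{M1,PM}, input->{cPM,cS1,cM1}) combination. All masks are
row = target, column = source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "REGIONS",
    "N_REGIONS",
    "NetworkLayout",
    "ModelSpec",
    "FamilyDefinition",
    "build_base_mask",
    "apply_s1_family",
    "apply_stim_family",
    "enumerate_model_space",
    "family_definitions",
    "model_space_to_json",
]

#: Fixed region order: contralateral block first, then ipsilateral.
REGIONS: Tuple[str, ...] = ("cM1", "cPM", "cSMA", "cS1", "iM1", "iPM", "iSMA", "iS1")
N_REGIONS = len(REGIONS)

_INDEX: Dict[str, int] = {r: i for i, r in enumerate(REGIONS)}


def region_index(label: str) -> int:
    """Index of *label* in the canonical region order."""
    try:
        return _INDEX[label]
    except KeyError:
        raise KeyError(f"unknown region label {label!r}; expected one of {REGIONS}") from None


@dataclass(frozen=True)
class NetworkLayout:
    """The eight-region bilateral layout and hemisphere assignment."""

    region_labels: Tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        if len(self.region_labels) != 8 or len(set(self.region_labels)) != 8:
            raise ValueError("layout requires exactly 8 unique region labels")
        sides = [lbl[0] for lbl in self.region_labels]
        if sides.count("c") != 4 or sides.count("i") != 4:
            raise ValueError("layout requires 4 contralateral and 4 ipsilateral regions")

    @property
    def hemisphere_of(self) -> Dict[str, str]:
        return {
            lbl: ("contra" if lbl.startswith("c") else "ipsi") for lbl in self.region_labels
        }


@dataclass(frozen=True)
class ModelSpec:
    """One network hypothesis: connectivity mask, input mask and family labels."""

    id: int
    s1_family: int
    stim_family: int
    a_mask: np.ndarray = field(repr=False)
    c_mask: np.ndarray = field(repr=False)
    region_labels: Tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        a = np.asarray(self.a_mask, dtype=bool)
        c = np.asarray(self.c_mask, dtype=bool)
        if a.shape != (8, 8) or c.shape != (8,):
            raise ValueError("a_mask must be 8x8 and c_mask length 8")
        if not np.all(np.diag(a)):
            raise ValueError("self-connections must be present in every model")
        if self.id != 3 * (self.s1_family - 1) + self.stim_family:
            raise ValueError("model id inconsistent with family indices")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "c_mask", c)

    @property
    def n_connections(self) -> int:
        """Allowed couplings, self-connections included; 28 for model 11."""
        return int(self.a_mask.sum())

    @property
    def n_inputs(self) -> int:
        return int(self.c_mask.sum())

    def connection_labels(self) -> List[str]:
        """Allowed couplings as ``source->target`` labels, sorted alphabetically."""
        labels = [
            f"{self.region_labels[j]}->{self.region_labels[i]}"
            for i in range(8)
            for j in range(8)
            if self.a_mask[i, j]
        ]
        return sorted(labels)


@dataclass(frozen=True)
class FamilyDefinition:
    """A named family: the subset of model ids sharing one factor level."""

    name: str
    member_model_ids: frozenset

    def __contains__(self, model_id: int) -> bool:
        return model_id in self.member_model_ids


@dataclass(frozen=True)
class ReducedModel:
    """A small custom network (any dimension) for reduced-system studies.

    Duck-type compatible with :class:`ModelSpec` where only the masks and
    region labels matter (simulation, inversion); not part of the 12-model
    space.
    """

    a_mask: np.ndarray
    c_mask: np.ndarray
    region_labels: Tuple[str, ...]
    id: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.a_mask, dtype=bool)
        c = np.asarray(self.c_mask, dtype=bool)
        n = len(self.region_labels)
        if a.shape != (n, n) or c.shape != (n,):
            raise ValueError("mask dimensions must match the region labels")
        if not np.all(np.diag(a)):
            raise ValueError("self-connections must be present")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "c_mask", c)


def build_base_mask() -> np.ndarray:
    """Base topology mask (row = target, column = source).

    Within each hemisphere every ordered pair among {M1, PM, SMA} is connected
    (6 directed edges per hemisphere); interhemispheric reciprocal edges join
    cM1/iM1 and cSMA/iSMA; all 8 self-loops are present; S1 has no edges.
    """
    mask = np.zeros((8, 8), dtype=bool)
    np.fill_diagonal(mask, True)
    for hemi in ("c", "i"):
        triple = [region_index(hemi + r) for r in ("M1", "PM", "SMA")]
        for i in triple:
            for j in triple:
                if i != j:
                    mask[i, j] = True
    for r in ("M1", "SMA"):
        a, b = region_index("c" + r), region_index("i" + r)
        mask[a, b] = mask[b, a] = True
    return mask


#: S1 efferent targets per family, mirrored over hemispheres.
_S1_TARGETS = {1: (), 2: ("M1",), 3: ("PM",), 4: ("M1", "PM")}

#: Contralateral regions driven by the input, per stimulus family.
_STIM_TARGETS = {1: ("cPM", "cS1"), 2: ("cPM", "cS1", "cM1"), 3: ("cS1", "cM1")}


def apply_s1_family(base_mask: np.ndarray, s1_family: int) -> np.ndarray:
    """Add the family's efferent S1 edges (both hemispheres) to *base_mask*.

    S1 only ever sends connections — to M1, PM, both, or neither — and never
    receives any, so the S1 columns gain entries while the S1 rows stay empty
    off the diagonal.
    """
    if s1_family not in _S1_TARGETS:
        raise ValueError(f"s1_family must be in 1..4, got {s1_family}")
    mask = np.array(base_mask, dtype=bool, copy=True)
    for hemi in ("c", "i"):
        src = region_index(hemi + "S1")
        for tgt in _S1_TARGETS[s1_family]:
            mask[region_index(hemi + tgt), src] = True
    return mask


def apply_stim_family(stim_family: int) -> np.ndarray:
    """Input mask for the stimulus-target family; only contralateral regions drive."""
    if stim_family not in _STIM_TARGETS:
        raise ValueError(f"stim_family must be in 1..3, got {stim_family}")
    c = np.zeros(8, dtype=bool)
    for lbl in _STIM_TARGETS[stim_family]:
        c[region_index(lbl)] = True
    return c


def enumerate_model_space() -> List[ModelSpec]:
    """All 12 models, ordered by id = 3*(s1_family-1) + stim_family."""
    base = build_base_mask()
    models = []
    for s1 in (1, 2, 3, 4):
        a = apply_s1_family(base, s1)
        for stim in (1, 2, 3):
            models.append(
                ModelSpec(
                    id=3 * (s1 - 1) + stim,
                    s1_family=s1,
                    stim_family=stim,
                    a_mask=a,
                    c_mask=apply_stim_family(stim),
                )
            )
    return models


def get_model(model_id: int) -> ModelSpec:
    """Fetch one model by id (1..12)."""
    if not 1 <= model_id <= 12:
        raise ValueError(f"model id must be in 1..12, got {model_id}")
    return enumerate_model_space()[model_id - 1]


def family_definitions() -> Tuple[List[FamilyDefinition], List[FamilyDefinition]]:
    """The two family sets: (S1-connection families, stimulus-target families).

    Each set partitions {1..12}: four S1 families of three models each, three
    stimulus families of four models each.
    """
    s1_fams = [
        FamilyDefinition(
            name=f"F_S1_{k}",
            member_model_ids=frozenset(3 * (k - 1) + s for s in (1, 2, 3)),
        )
        for k in (1, 2, 3, 4)
    ]
    stim_fams = [
        FamilyDefinition(
            name=f"F_stim_{k}",
            member_model_ids=frozenset(3 * (s1 - 1) + k for s1 in (1, 2, 3, 4)),
        )
        for k in (1, 2, 3)
    ]
    return s1_fams, stim_fams


def model_space_to_json(path=None) -> str:
    """Serialize the model space (masks as nested 0/1 arrays) to JSON."""
    doc = {
        "region_labels": list(REGIONS),
        "mask_convention": "row = target, column = source",
        "models": [
            {
                "id": m.id,
                "s1_family": m.s1_family,
                "stim_family": m.stim_family,
                "a_mask": m.a_mask.astype(int).tolist(),
                "c_mask": m.c_mask.astype(int).tolist(),
            }
            for m in enumerate_model_space()
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
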