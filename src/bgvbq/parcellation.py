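"""Connectivity-based parcellation of the seed nucleus.

Per-target streamline counts are aggregated into motor / associative /
limbic class maps, z-scored over seed voxels within subject (population-SD
convention), and turned into exclusive parcels by the winner-takes-all rule
after subtracting the other classes' values: e_c = z_c - sum_{c' != c} z_c'.
For three classes argmax_c e_c coincides with argmax_c z_c (the subtraction
adds the class-independent constant -sum_all z); both are stored so either
reading is inspectable. Exact ties are left unassigned (label 0).

The bipartite variant first merges the limbic and associative z maps by
voxel-wise mean into one "limbic_associative" class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import ConnectivityMaps

CLASSES = ("motor", "associative", "limbic")
BIPARTITE_CLASSES = ("motor", "limbic_associative")

#: default mapping of phantom-atlas targets to connectivity classes
DEFAULT_CLASS_DEF = {
    "m1": "motor",
    "sma": "motor",
    "superior_frontal": "associative",
    "middle_frontal": "associative",
    "acc": "limbic",
    "ofc": "limbic",
    "hippocampus_l": "limbic",
    "hippocampus_r": "limbic",
    "amygdala_l": "limbic",
    "amygdala_r": "limbic",
}


@dataclass
class ClassMapSet:
    """Per-class values over seed voxels (raw counts or z-scores)."""

    values: dict[str, np.ndarray]  # class -> (n_seed,)
    seed_voxels: np.ndarray  # (n_seed, 3) int
    shape: tuple[int, ...]
    affine: np.ndarray
    zscored: bool = False
    degenerate: set[str] = field(default_factory=set)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def volume(self, cls: str) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.float64)
        vol[tuple(self.seed_voxels.T)] = self.values[cls]
        return vol


@dataclass
class ParcelMap:
    """Exclusive parcel labels over seed voxels (0 = unassigned tie)."""

    labels: np.ndarray  # (n_seed,) int, 1-based index into class_names
    exclusive: dict[str, np.ndarray]  # class -> e_c = z_c - sum(others)
    class_names: tuple[str, ...]
    seed_voxels: np.ndarray
    shape: tuple[int, ...]
    affine: np.ndarray

    def label_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.int16)
        vol[tuple(self.seed_voxels.T)] = self.labels
        return vol

    def mask_of(self, cls: str) -> np.ndarray:
        value = self.class_names.index(cls) + 1
        vol = np.zeros(self.shape, dtype=bool)
        vol[tuple(self.seed_voxels.T)] = self.labels == value
        return vol

    def sizes(self) -> dict[str, int]:
        out = {c: int((self.labels == i + 1).sum())
               for i, c in enumerate(self.class_names)}
        out["unassigned"] = int((self.labels == 0).sum())
        return out


def aggregate_classes(conn: ConnectivityMaps,
                      class_def: dict[str, str] | None = None) -> ClassMapSet:
    """Sum member-target count maps into per-class raw maps."""
    if class_def is None:
        class_def = DEFAULT_CLASS_DEF
    missing = [t for t in conn.counts if t not in class_def]
    if missing:
        raise KeyError(f"targets missing from class definition: {missing}")
    classes = [c for c in dict.fromkeys(class_def.values())]
    n = len(conn.seed_voxels)
    values = {c: np.zeros(n, dtype=np.float64) for c in classes}
    for target, counts in conn.counts.items():
        values[class_def[target]] += counts
    return ClassMapSet(values=values, seed_voxels=conn.seed_voxels,
                       shape=conn.shape, affine=conn.affine)


def zscore_maps(raw: ClassMapSet) -> ClassMapSet:
    """Z-score each class map over seed voxels (population SD, ddof=0).

    A class whose map is constant has no connectivity contrast; it is set to
    all zeros and flagged degenerate.
    """
    values, degenerate = {}, set()
    for cls, v in raw.values.items():
        sd = v.std()  # population convention
        if sd == 0:
            values[cls] = np.zeros_like(v)
            degenerate.add(cls)
        else:
            values[cls] = (v - v.mean()) / sd
    return ClassMapSet(values=values, seed_voxels=raw.seed_voxels,
                       shape=raw.shape, affine=raw.affine,
                       zscored=True, degenerate=degenerate)


def winner_takes_all(z: ClassMapSet, mode: str = "tripartite") -> ParcelMap:
    """Exclusive winner-takes-all parcel from z-scored class maps."""
    if mode == "tripartite":
        values = dict(z.values)
    elif mode == "bipartite":
        values = {
            "motor": z.values["motor"],
            "limbic_associative": 0.5 * (z.values["limbic"]
                                         + z.values["associative"]),
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    names = tuple(values)
    if z.degenerate >= set(z.values):
        raise ValueError("all class maps are degenerate; cannot parcellate")
    stack = np.stack([values[c] for c in names], axis=0)  # (C, n)
    total = stack.sum(axis=0)
    exclusive = {c: stack[i] - (total - stack[i]) for i, c in enumerate(names)}
    order = np.argsort(stack, axis=0)
    best = order[-1]
    top = np.take_along_axis(stack, best[None], axis=0)[0]
    second = np.take_along_axis(stack, order[-2][None], axis=0)[0]
    labels = (best + 1).astype(np.int16)
    labels[top == second] = 0  # exact ties stay unassigned
    return ParcelMap(labels=labels, exclusive=exclusive, class_names=names,
                     seed_voxels=z.seed_voxels, shape=z.shape, affine=z.affine)


def group_average_parcel(subject_maps: list[ClassMapSet],
                         mode: str = "tripartite") -> ParcelMap:
    """Voxel-wise mean of subject z maps per class, then winner-takes-all."""
    if not subject_maps:
        raise ValueError("need at least one subject map set")
    first = subject_maps[0]
    for m in subject_maps[1:]:
        if not np.array_equal(m.seed_voxels, first.seed_voxels):
            raise ValueError("subjects must share the seed voxel grid")
    values = {c: np.mean([m.values[c] for m in subject_maps], axis=0)
              for c in first.class_names}
    mean_set = ClassMapSet(values=values, seed_voxels=first.seed_voxels,
                           shape=first.shape, affine=first.affine,
                           zscored=True,
                           degenerate=set.intersection(
                               *[m.degenerate for m in subject_maps])
                           if any(m.degenerate for m in subject_maps) else set())
    return winner_takes_all(mean_set, mode=mode)


def parcellate_counts(conn: ConnectivityMaps,
                      class_def: dict[str, str] | None = None,
                      mode: str = "tripartite") -> ParcelMap:
    """Convenience chain: aggregate -> z-score -> winner-takes-all."""
    return winner_takes_all(zscore_maps(aggregate_classes(conn, class_def)),
                            mode=mode)
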