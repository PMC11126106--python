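"""Block dataset construction: tiling, case-level splits, augmentation, balance.

A *block* is a fixed-size square spatial patch with full spectral depth; it is
the classification unit.  Blocks are cut on a stride grid and kept only when a
single nodule code (benign or malignant) covers at least ``purity`` of their
footprint, so that under the default purity of 1.0 every block lies entirely
inside one nodule.  Splits are made at the case (patient) level, stratified by
diagnosis, so no patient contributes blocks to more than one partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from thyrospec.errors import LeakageError, ShapeError
from thyrospec.hsi_io import BENIGN, HyperCube, LabelMask, MALIGNANT, NODULE_CLASS

CLASS_NAMES = ("benign", "malignant")


@dataclass
class Block:
    """One spatial patch with full spectral depth and provenance."""

    data: np.ndarray          # (h, w, B)
    label: int                # 0 = benign, 1 = malignant
    case_id: str
    origin: tuple[int, int]   # 0-based (row, col) of the top-left pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError("block data must be (h, w, B)")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (malignant)")


@dataclass
class SplitPlan:
    """Case-id partition into train/validation/test, stratified by diagnosis."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise LeakageError(f"case ids in two partitions: {sorted(overlap)}")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


@dataclass
class BlockDataset:
    """A list of blocks plus class counts and balancing weights."""

    blocks: list[Block]
    class_counts: tuple[int, int] = (0, 0)
    weights: tuple[float, float] = (1.0, 1.0)
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_blocks(cls, blocks: list[Block], **meta) -> "BlockDataset":
        counts = (sum(b.label == 0 for b in blocks),
                  sum(b.label == 1 for b in blocks))
        if min(counts) > 0:
            w = class_weights(counts)
        else:
            w = (1.0, 1.0)
        return cls(blocks=blocks, class_counts=counts, weights=tuple(w), meta=meta)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def case_ids(self) -> set[str]:
        return {b.case_id for b in self.blocks}

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Blocks as one (N, h, w, B) tensor plus an (N,) label vector."""
        if not self.blocks:
            return (np.zeros((0, 0, 0, 0), dtype=np.float32),
                    np.zeros(0, dtype=np.int64))
        x = np.stack([b.data for b in self.blocks]).astype(np.float32)
        y = np.array([b.label for b in self.blocks], dtype=np.int64)
        return x, y

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        x, y = self.stacked()
        with h5py.File(str(path), "w") as f:
            f.create_dataset("blocks", data=x)
            f.create_dataset("labels", data=y)
            f.create_dataset("case_ids",
                             data=np.array([b.case_id for b in self.blocks], dtype="S"))
            f.create_dataset("origins",
                             data=np.array([b.origin for b in self.blocks],
                                           dtype=np.int64).reshape(-1, 2))
        manifest = dict(self.meta)
        manifest.update({
            "n_blocks": len(self.blocks),
            "class_counts": list(self.class_counts),
            "class_weights": list(self.weights),
        })
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BlockDataset":
        path = Path(path)
        with h5py.File(str(path), "r") as f:
            x = f["blocks"][()]
            y = f["labels"][()]
            ids = [s.decode() for s in f["case_ids"][()]]
            origins = f["origins"][()]
        blocks = [Block(x[i], int(y[i]), ids[i], tuple(int(v) for v in origins[i]))
                  for i in range(len(y))]
        meta = {}
        mpath = path.with_suffix(path.suffix + ".json")
        if mpath.exists():
            meta = json.loads(mpath.read_text())
        return cls.from_blocks(blocks, **{k: v for k, v in meta.items()
                                          if k not in ("n_blocks", "class_counts",
                                                       "class_weights")})


def crop_blocks(cube: HyperCube | np.ndarray, mask: LabelMask | np.ndarray,
                size: int, stride: int | None = None,
                purity: float = 1.0) -> list[Block]:
    """Tile a labelled cube into blocks on a stride grid.

    Origins are enumerated row-major; a block is kept iff the fraction of its
    footprint labelled with a single nodule code (benign or malignant) is at
    least ``purity``.  With ``purity <= 0.5`` both codes may qualify; the one
    with the larger count wins (ties to benign).  Oversized blocks yield an
    empty list.
    """
    data = cube.data if isinstance(cube, HyperCube) else np.asarray(cube)
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if data.shape[:2] != labels.shape:
        raise ShapeError("cube spatial shape must match mask")
    if stride is None:
        stride = size
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    rows, cols = labels.shape
    area = size * size
    out: list[Block] = []
    if size > rows or size > cols:
        return out
    for r in range(0, rows - size + 1, stride):
        for c in range(0, cols - size + 1, stride):
            window = labels[r:r + size, c:c + size]
            counts = {code: int((window == code).sum())
                      for code in (BENIGN, MALIGNANT)}
            qualifying = [code for code in (BENIGN, MALIGNANT)
                          if counts[code] >= purity * area]
            if not qualifying:
                continue
            code = max(qualifying, key=lambda k: (counts[k], -k))
            out.append(Block(data[r:r + size, c:c + size].copy(),
                             NODULE_CLASS[code], getattr(cube, "case_id", ""),
                             (r, c)))
    return out


def split_by_case(cases, train_frac: float = 0.7,
                  val_frac_of_train: float = 1 / 7, seed: int = 0) -> SplitPlan:
    """Stratified random case-level split into train/validation/test.

    ``cases`` may be any records exposing ``case_id`` and ``diagnosis``
    attributes.  Assignment is per diagnosis stratum with round-to-nearest
    counts, then adjusted so the overall train size equals
    ``round(train_frac * n)``; a further ``val_frac_of_train`` of the training
    cases (stratified) is flagged as validation.  Deterministic given seed.
    """
    import warnings

    strata: dict[str, list[str]] = {}
    for case in cases:
        strata.setdefault(case.diagnosis, []).append(case.case_id)
    n_total = sum(len(v) for v in strata.values())
    rng = np.random.default_rng(seed)
    for diag, ids in sorted(strata.items()):
        if len(ids) < 3:
            warnings.warn(f"stratum {diag!r} has only {len(ids)} case(s); "
                          "best-effort split", stacklevel=2)

    # train counts per stratum, corrected to hit the global target exactly;
    # the stratum to adjust is the one with the largest rounding surplus
    # (deficit), with ties broken by the seeded generator so no diagnosis is
    # systematically favoured
    target_train = round(train_frac * n_total)
    names = sorted(strata)
    order = list(names)
    rng.shuffle(order)
    n_train = {d: round(train_frac * len(strata[d])) for d in names}
    while sum(n_train.values()) != target_train:
        delta = int(np.sign(target_train - sum(n_train.values())))
        surplus = {d: n_train[d] - train_frac * len(strata[d]) for d in order}
        candidates = [d for d in order
                      if 0 <= n_train[d] + delta <= len(strata[d])]
        d = (min if delta > 0 else max)(candidates, key=lambda d: surplus[d])
        n_train[d] += delta

    train_ids: list[str] = []
    val_ids: list[str] = []
    test_ids: list[str] = []
    for d in names:
        ids = sorted(strata[d])
        rng.shuffle(ids)
        tr = ids[:n_train[d]]
        test_ids.extend(ids[n_train[d]:])
        n_val = round(val_frac_of_train * len(tr))
        val_ids.extend(tr[:n_val])
        train_ids.extend(tr[n_val:])
    return SplitPlan(train_ids=train_ids, val_ids=val_ids, test_ids=test_ids,
                     seed=seed)


def augment(block: Block, ops: dict | None = None, seed: int = 0) -> Block:
    """Seeded spatial augmentation: random horizontal/vertical flips and crop.

    ``ops`` keys: ``hflip``/``vflip`` (application probabilities, default 0.5)
    and ``crop`` (target spatial size for a random crop).  The spectral axis,
    label and provenance are untouched.
    """
    ops = {"hflip": 0.5, "vflip": 0.5} if ops is None else dict(ops)
    rng = np.random.default_rng(seed)
    data = block.data
    origin = block.origin
    if rng.random() < ops.get("hflip", 0.0):
        data = data[:, ::-1, :]
    if rng.random() < ops.get("vflip", 0.0):
        data = data[::-1, :, :]
    crop = ops.get("crop")
    if crop is not None:
        h, w = data.shape[:2]
        if crop > h or crop > w:
            raise ValueError(f"crop {crop} exceeds block size {(h, w)}")
        r = int(rng.integers(0, h - crop + 1))
        c = int(rng.integers(0, w - crop + 1))
        data = data[r:r + crop, c:c + crop, :]
        origin = (origin[0] + r, origin[1] + c)
    return Block(np.ascontiguousarray(data), block.label, block.case_id, origin)


def class_weights(counts) -> np.ndarray:
    """Loss weights inversely proportional to class counts, mean-1 normalized."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 1).any():
        raise ValueError(f"all class counts must be >= 1, got {counts}")
    w = 1.0 / counts
    return w * counts.size / w.sum()
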