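"""Dataset manifests, image/mask loading and the two split protocols.

A manifest is an ordered list of records (image path, mask path, source
dataset, split tag) serialized as a CSV with header ``image,mask,source,split``.

Two protocols are provided:

* **standard** — per source dataset, 10% is held out for testing (100 of
  1000 Kvasir-SEG records, 62 of 612 CVC-ClinicDB records); the remaining
  records form a combined training pool (1450 at full size) from which a
  10% validation subsample is drawn.  Published per-dataset summaries count
  the validation images inside the training column, which is why their rows
  over-count; here the three split tags always partition the records.
* **merged** — all five datasets are pooled (2248 records at full size),
  shuffled, and 224 records are assigned to test and to validation each,
  the remainder to training.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["SampleRecord", "DatasetManifest", "load_sample",
           "split_standard", "split_merged"]


@dataclass(frozen=True)
class SampleRecord:
    image: str
    mask: str
    source: str
    split: str = "train"

    def with_split(self, split: str) -> "SampleRecord":
        return SampleRecord(self.image, self.mask, self.source, split)


@dataclass
class DatasetManifest:
    records: list[SampleRecord]
    protocol: str = ""
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> list[SampleRecord]:
        return [r for r in self.records if r.split == split]

    @property
    def splits(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.split] = counts.get(r.split, 0) + 1
        return counts

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "mask", "source", "split"])
            for r in self.records:
                writer.writerow([r.image, r.mask, r.source, r.split])

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or \
                    not {"image", "mask", "source", "split"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: manifest needs header image,mask,source,split")
            for row in reader:
                records.append(SampleRecord(row["image"], row["mask"],
                                            row["source"], row["split"]))
        return cls(records)


def load_sample(record: SampleRecord, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Read and preprocess one image/mask pair.

    The image is bilinearly resized to ``size`` x ``size``, scaled to [0, 1]
    and normalized as (v − 0.5)/0.5, giving the range [−1, 1].  The mask is
    nearest-neighbor resized and binarized at 127/255.

    Returns ``(image (3,H,W) float32, mask (1,H,W) float32 in {0,1})``.
    """
    try:
        img = Image.open(record.image).convert("RGB")
    except Exception as exc:
        raise OSError(f"cannot read image {record.image}: {exc}") from exc
    try:
        msk = Image.open(record.mask).convert("L")
    except Exception as exc:
        raise OSError(f"cannot read mask {record.mask}: {exc}") from exc
    if img.size != msk.size:
        raise ValueError(f"image {record.image} is {img.size} but mask "
                         f"{record.mask} is {msk.size}")
    img = img.resize((size, size), Image.BILINEAR)
    msk = msk.resize((size, size), Image.NEAREST)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    arr = (arr - 0.5) / 0.5
    mask = (np.asarray(msk, dtype=np.float32) > 127).astype(np.float32)
    return arr.transpose(2, 0, 1), mask[None]


def _shuffled(records: list[SampleRecord], rng: np.random.Generator) -> list[SampleRecord]:
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def split_standard(kvasir: DatasetManifest, clinicdb: DatasetManifest,
                   seed: int = 0) -> DatasetManifest:
    """Standard protocol: per-source 10% test, combined pool, 10% validation."""
    if not len(kvasir) or not len(clinicdb):
        raise ValueError("both manifests must be nonempty")
    rng = np.random.default_rng(seed)
    pool: list[SampleRecord] = []
    test: list[SampleRecord] = []
    for manifest in (kvasir, clinicdb):
        records = _shuffled(list(manifest.records), rng)
        n_test = math.ceil(0.10 * len(records))
        test += [r.with_split("test") for r in records[:n_test]]
        pool += records[n_test:]
    pool = _shuffled(pool, rng)
    n_valid = math.ceil(0.10 * len(pool))
    valid = [r.with_split("valid") for r in pool[:n_valid]]
    train = [r.with_split("train") for r in pool[n_valid:]]
    out = DatasetManifest(train + valid + test, protocol="standard", seed=seed)
    out.extra["train_pool"] = len(pool)  # train + valid, before the subsample
    return out


def split_merged(manifests: list[DatasetManifest], seed: int = 0,
                 n_test: int = 224, n_valid: int = 224) -> DatasetManifest:
    """Merged protocol: one shuffled pool, fixed-size test and validation sets."""
    records: list[SampleRecord] = []
    for m in manifests:
        records += list(m.records)
    if len(records) < n_test + n_valid:
        raise ValueError(f"pool of {len(records)} records is smaller than "
                         f"test+valid = {n_test + n_valid}")
    rng = np.random.default_rng(seed)
    records = _shuffled(records, rng)
    test = [r.with_split("test") for r in records[:n_test]]
    valid = [r.with_split("valid") for r in records[n_test:n_test + n_valid]]
    train = [r.with_split("train") for r in records[n_test + n_valid:]]
    out = DatasetManifest(train + valid + test, protocol="merged", seed=seed)
    out.extra["pool"] = len(records)
    return out
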