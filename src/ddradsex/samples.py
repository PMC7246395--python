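"""Sample sheets: sample id, sex label, inline barcode."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

VALID_SEXES = ("M", "F")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str  # "M" or "F"
    barcode: str

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"sample {self.sample_id!r}: sex must be one of {VALID_SEXES}, got {self.sex!r}"
            )
        if not self.barcode or any(b not in "ACGT" for b in self.barcode):
            raise ValueError(f"sample {self.sample_id!r}: invalid barcode {self.barcode!r}")


def validate_samples(samples: list[Sample]) -> None:
    """Reject duplicate sample ids, barcode collisions and unequal barcode lengths."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sample sheet")
    barcodes = [s.barcode for s in samples]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcode collision in sample sheet")
    if len({len(b) for b in barcodes}) > 1:
        raise ValueError("barcodes must all have the same length")


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read a TSV of (sample_id, sex, barcode); '#' lines and a header row are skipped."""
    samples = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "sample_id":  # header
            continue
        if len(fields) != 3:
            raise ValueError(f"sample sheet row needs 3 tab-separated fields: {line!r}")
        samples.append(Sample(*fields))
    validate_samples(samples)
    return samples


def write_sample_sheet(samples: list[Sample], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\tbarcode\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.barcode}\n")


def sex_of(samples: list[Sample]) -> dict[str, str]:
    return {s.sample_id: s.sex for s in samples}
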