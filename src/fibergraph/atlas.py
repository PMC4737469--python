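"""Parcellation atlas: the 90-region cortical/subcortical node definition.

Nodes of every connectivity network are the 90 cerebral regions of the AAL
parcellation.  Region indices are 1-based and follow the standard convention
that odd indices are left-hemisphere and even indices right-hemisphere; the
homologous pair shares a name and abbreviation, disambiguated as ``ABBR.L`` /
``ABBR.R``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["AtlasError", "RoiEntry", "RoiAtlas", "load_atlas", "N_NODES"]

#: Number of parcellation regions (cerebrum only).
N_NODES = 90

_HEMISPHERES = {"left", "right"}


class AtlasError(ValueError):
    """Raised when an atlas table violates the parcellation contract."""


@dataclass(frozen=True)
class RoiEntry:
    """One parcellation region."""

    index: int  # 1-based atlas index
    name: str
    abbreviation: str
    hemisphere: str  # "left" | "right"

    @property
    def label(self) -> str:
        """Hemisphere-qualified abbreviation, e.g. ``PCUN.L``."""
        suffix = "L" if self.hemisphere == "left" else "R"
        return f"{self.abbreviation}.{suffix}"


class RoiAtlas:
    """Ordered table of the 90 parcellation regions.

    Invariants enforced at construction:

    * exactly 90 entries, indices 1..90 without gaps or duplicates;
    * odd indices are left-hemisphere, even indices right;
    * hemisphere-qualified abbreviations are unique.
    """

    def __init__(self, entries: Iterable[RoiEntry]):
        entries = sorted(entries, key=lambda e: e.index)
        if len(entries) != N_NODES:
            raise AtlasError(
                f"atlas must have exactly {N_NODES} entries, got {len(entries)}"
            )
        for pos, entry in enumerate(entries, start=1):
            if entry.index != pos:
                raise AtlasError(
                    f"atlas indices must be 1..{N_NODES} without gaps; "
                    f"expected {pos}, found {entry.index}"
                )
            if entry.hemisphere not in _HEMISPHERES:
                raise AtlasError(
                    f"row {entry.index}: hemisphere must be left|right, "
                    f"got {entry.hemisphere!r}"
                )
            expected = "left" if entry.index % 2 == 1 else "right"
            if entry.hemisphere != expected:
                raise AtlasError(
                    f"row {entry.index}: odd indices are left-hemisphere, even "
                    f"are right; got {entry.hemisphere!r}"
                )
        labels = [e.label for e in entries]
        if len(set(labels)) != N_NODES:
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise AtlasError(f"duplicate hemisphere-qualified abbreviations: {dupes}")
        self.entries: tuple[RoiEntry, ...] = tuple(entries)
        self._by_label = {e.label: e.index for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, index: int) -> RoiEntry:
        """Entry by 1-based atlas index."""
        if not 1 <= index <= N_NODES:
            raise KeyError(f"atlas index must be in 1..{N_NODES}, got {index}")
        return self.entries[index - 1]

    def __iter__(self):
        return iter(self.entries)

    @property
    def labels(self) -> list[str]:
        """Hemisphere-qualified abbreviations in atlas order."""
        return [e.label for e in self.entries]

    def index_of(self, label: str) -> int:
        """1-based index of a hemisphere-qualified abbreviation."""
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown ROI label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self.entries],
                "name": [e.name for e in self.entries],
                "abbreviation": [e.abbreviation for e in self.entries],
                "hemisphere": [e.hemisphere for e in self.entries],
            }
        )


def _default_atlas_path() -> Path:
    return Path(resources.files("fibergraph") / "data" / "aal90.tsv")


def load_atlas(path: str | Path | None = None) -> RoiAtlas:
    """Load and validate a parcellation table.

    Parameters
    ----------
    path
        Tab-separated file with columns ``index``, ``name``, ``abbreviation``
        and optionally ``hemisphere`` (inferred from index parity when
        absent).  ``None`` loads the packaged 90-region default.
    """
    src = _default_atlas_path() if path is None else Path(path)
    try:
        table = pd.read_csv(src, sep="\t", dtype=str)
    except Exception as exc:  # malformed file
        raise AtlasError(f"cannot parse atlas file {src}: {exc}") from exc
    required = {"index", "name", "abbreviation"}
    missing = required - set(table.columns)
    if missing:
        raise AtlasError(f"atlas file {src} missing columns: {sorted(missing)}")

    entries = []
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        try:
            idx = int(row.index)
        except (TypeError, ValueError):
            raise AtlasError(
                f"{src} line {row_no}: non-integer index {row.index!r}"
            ) from None
        hemi = (
            getattr(row, "hemisphere", None)
            or ("left" if idx % 2 == 1 else "right")
        )
        entries.append(
            RoiEntry(
                index=idx,
                name=str(row.name).strip(),
                abbreviation=str(row.abbreviation).strip(),
                hemisphere=str(hemi).strip().lower(),
            )
        )
    seen: set[int] = set()
    for e in entries:
        if e.index in seen:
            raise AtlasError(f"{src}: duplicate atlas index {e.index}")
        seen.add(e.index)
    return RoiAtlas(entries)
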