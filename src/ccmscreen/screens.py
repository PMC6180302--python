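"""Screen results: activity calls over a fingerprinted compound set."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .compounds import Fingerprint


@dataclass
class ScreenResult:
    """Per-screen activity labels over a (deduplicated) compound set.

    ``fingerprints`` maps canonical compound id -> Fingerprint; ``active``
    is the subset of ids called active in this screen.
    """

    screen_id: str
    fingerprints: dict
    active: set = field(default_factory=set)

    def __post_init__(self):
        stray = set(self.active) - set(self.fingerprints)
        if stray:
            raise ValueError(
                f"screen {self.screen_id!r}: active ids not in compound set: "
                f"{sorted(stray)[:5]}"
            )

    @property
    def ids(self) -> set:
        return set(self.fingerprints)

    @property
    def n_compounds(self) -> int:
        return len(self.fingerprints)

    @property
    def n_active(self) -> int:
        return len(self.active)


def write_screen_tsv(screen: ScreenResult, path) -> None:
    """TSV: compound_id TAB active(0/1)."""
    with open(path, "w") as fh:
        fh.write("compound_id\tactive\n")
        for cid in sorted(screen.fingerprints):
            fh.write(f"{cid}\t{int(cid in screen.active)}\n")


def read_screen_tsv(path, fingerprints: dict, screen_id: str = "") -> ScreenResult:
    """Read activity labels; fingerprints are supplied by the caller
    (typically from the library TSV)."""
    active = set()
    ids = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#") or line.startswith("compound_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(f"{path}:{line_no}: expected 'compound_id<TAB>0|1'")
        cid, flag = parts
        ids.add(cid)
        if flag == "1":
            active.add(cid)
    missing = ids - set(fingerprints)
    if missing:
        raise ValueError(f"{path}: no fingerprint for ids {sorted(missing)[:5]}")
    return ScreenResult(
        screen_id=screen_id or Path(path).stem,
        fingerprints={cid: fingerprints[cid] for cid in ids},
        active=active,
    )
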