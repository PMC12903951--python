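"""Adapter/primer (AP) schemas and kit presets.

An ONT cDNA library molecule, in sense orientation, reads

    front_ap + insert + polyA + revcomp(rear_ap)

so on a plus-strand read the front AP is matched directly near the 5' end and
the rear AP is matched as its reverse complement near the 3' end; a
minus-strand read is the reverse complement of the whole construct. AP
substrings used for alignment always retain the insert-proximal end of the AP,
so the trimming boundary (AP/insert junction) is part of every alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .seqio import revcomp

_AP_ALPHABET = frozenset("ACGT")

FRONT = "front"
REAR = "rear"
AP_IDS = (FRONT, REAR)


@dataclass(frozen=True)
class APSchema:
    """Front/rear adapter-primer pair for one library construction kit.

    ``front_ap`` is the AP expected at the 5' end of the sense-oriented read;
    ``rear_ap`` is given in sense orientation, so its reverse complement is what
    appears at the 3' end of a plus-strand read. The polyA tail sits on the
    rear side (between insert and rear AP) for all supported cDNA kits.
    """

    kit_name: str
    front_ap: str
    rear_ap: str
    polya_side: str = "rear"

    def __post_init__(self) -> None:
        for name, ap in (("front_ap", self.front_ap), ("rear_ap", self.rear_ap)):
            if not ap:
                raise ValueError(f"{name} must be nonempty")
            if not set(ap) <= _AP_ALPHABET:
                raise ValueError(f"{name} contains bases outside ACGT: {ap}")
        if self.polya_side != "rear":
            raise ValueError("only polya_side='rear' is supported for cDNA kits")

    def ap_sequence(self, ap_id: str) -> str:
        if ap_id == FRONT:
            return self.front_ap
        if ap_id == REAR:
            return self.rear_ap
        raise ValueError(f"unknown ap_id {ap_id!r}")

    def pattern(self, ap_id: str, strand: str, length: int | None = None) -> str:
        """Alignment pattern for one AP end, strand and substring length.

        Substrings keep the insert-proximal end of the AP (the 3' end of the
        front AP; the polyA-adjacent end of the rear AP), so the AP/insert
        boundary is always inside the aligned interval.
        """
        ap = self.ap_sequence(ap_id)
        if length is None:
            length = len(ap)
        if not 1 <= length <= len(ap):
            raise ValueError(f"substring length {length} outside [1, {len(ap)}]")
        core = ap[-length:]
        if ap_id == REAR:
            # as seen on a plus-strand read the rear AP is reverse-complemented
            core = revcomp(core)
        if strand == "+":
            return core
        if strand == "-":
            return revcomp(core)
        raise ValueError(f"unknown strand {strand!r}")


def end_distance(ap_id: str, strand: str, read_start: int, read_end: int,
                 read_length: int) -> int:
    """Distance from an AP hit to its expected terminus on the oriented read.

    The front AP is expected at the 5' end of the sense read, the rear AP at
    the 3' end; a minus-strand hit maps to the opposite end of the forward
    read. Distances are absolute base counts, independent of read length.
    """
    if (ap_id == FRONT) == (strand == "+"):
        return read_start
    return read_length - read_end


def available_kits() -> list[str]:
    root = resources.files("ontprep").joinpath("data/kits")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_kit(kit_name: str) -> APSchema:
    """Load a shipped kit preset (e.g. ``PCS109``) as an :class:`APSchema`."""
    path = resources.files("ontprep").joinpath(f"data/kits/{kit_name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ValueError(
            f"unknown kit preset {kit_name!r}; available: "
            f"{', '.join(available_kits())}. For other kits supply the primer "
            "sequences directly (front/rear AP)."
        ) from None
    data = yaml.safe_load(text)
    return APSchema(
        kit_name=data.get("kit_name", kit_name),
        front_ap=str(data["front_ap"]).upper(),
        rear_ap=str(data["rear_ap"]).upper(),
        polya_side=data.get("polya_side", "rear"),
    )
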