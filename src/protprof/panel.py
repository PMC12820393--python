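"""The fluorogenic substrate panel.

The assay probes stool extracts with short peptide–AMC conjugates.  Each
peptide motif is preferentially cleaved by one protease class — serine
(elastase-like, furin-like, SKI-1/S1P-like, trypsin-like) or cysteine
(cathepsin-like) — and releases the AMC fluorophore on cleavage of the
terminal bond, so fluorescence accumulation reports motif-specific
proteolytic activity.  The packaged panel ships the study's 14 substrates
with their class, subclass, pH-optimum range, and derivation (the epithelial
/ inflammation-related proteins the custom sequences were taken from,
carried as metadata only).

Substrate naming in the literature drifts (the same peptide appears with and
without its N-terminal residue, or without its Ac-/Pyr- prefix); known
aliases are recorded per entry but deliberately not resolved to a canonical
form beyond the packaged ``substrate_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from ._errors import FormatError, InputError

__all__ = ["SubstrateEntry", "SubstratePanel", "load_substrate_panel"]

PROTEASE_CLASSES = ("serine", "cysteine")
SUBCLASSES = (
    "elastase-like",
    "furin-like",
    "SKI-1/S1P-like",
    "trypsin-like",
    "cathepsin-like",
)
#: cathepsin-like is the only cysteine subclass; every other subclass is serine.
_CLASS_OF_SUBCLASS = {s: ("cysteine" if s == "cathepsin-like" else "serine") for s in SUBCLASSES}


@dataclass(frozen=True)
class SubstrateEntry:
    substrate_id: str
    sequence: str
    protease_class: str
    subclass: str
    ph_opt_low: float | None
    ph_opt_high: float | None
    custom: bool
    derivation: str = ""
    aliases: tuple[str, ...] = ()

    def ph_in_optimum(self, ph: float) -> bool:
        """Whether ``ph`` falls in the substrate's optimum range.

        Substrates without a recorded range are treated as active at any pH.
        """
        if self.ph_opt_low is None or self.ph_opt_high is None:
            return True
        return self.ph_opt_low <= ph <= self.ph_opt_high


class SubstratePanel:
    """An ordered, validated collection of substrate entries."""

    def __init__(self, entries: list[SubstrateEntry]):
        ids = [e.substrate_id for e in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate substrate ids: {dupes}")
        for e in entries:
            if e.protease_class not in PROTEASE_CLASSES:
                raise FormatError(
                    f"{e.substrate_id}: unknown protease class {e.protease_class!r}"
                )
            if e.subclass not in SUBCLASSES:
                raise FormatError(f"{e.substrate_id}: unknown subclass {e.subclass!r}")
            if _CLASS_OF_SUBCLASS[e.subclass] != e.protease_class:
                raise FormatError(
                    f"{e.substrate_id}: subclass {e.subclass!r} is inconsistent "
                    f"with class {e.protease_class!r}"
                )
        self.entries = list(entries)
        self._by_id = {e.substrate_id: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, substrate_id: str) -> bool:
        return substrate_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [e.substrate_id for e in self.entries]

    def entry(self, substrate_id: str) -> SubstrateEntry:
        try:
            return self._by_id[substrate_id]
        except KeyError:
            raise InputError(f"substrate {substrate_id!r} not in panel") from None

    def class_of(self, substrate_id: str) -> str:
        return self.entry(substrate_id).protease_class

    def ids_of_class(self, protease_class: str) -> list[str]:
        return [e.substrate_id for e in self.entries if e.protease_class == protease_class]

    def subset(self, substrate_ids: list[str]) -> "SubstratePanel":
        return SubstratePanel([self.entry(s) for s in substrate_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substrate_id": [e.substrate_id for e in self.entries],
                "sequence": [e.sequence for e in self.entries],
                "protease_class": [e.protease_class for e in self.entries],
                "subclass": [e.subclass for e in self.entries],
                "ph_opt_low": [e.ph_opt_low for e in self.entries],
                "ph_opt_high": [e.ph_opt_high for e in self.entries],
                "custom": [e.custom for e in self.entries],
                "derivation": [e.derivation for e in self.entries],
                "aliases": [";".join(e.aliases) for e in self.entries],
            }
        )


def _parse_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_substrate_panel(source: str | Path | None = None) -> SubstratePanel:
    """Load a substrate panel from a TSV/CSV file, or the packaged 14-substrate panel.

    Expected columns: ``substrate_id, sequence, protease_class, subclass,
    ph_opt_low, ph_opt_high, custom`` and optionally ``derivation, aliases``
    (aliases semicolon-separated).
    """
    if source is None:
        ref = resources.files("protprof.data").joinpath("substrate_panel.tsv")
        with resources.as_file(ref) as path:
            return load_substrate_panel(path)
    source = Path(source)
    sep = "\t" if source.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(source, sep=sep, dtype=str)
    required = {"substrate_id", "sequence", "protease_class", "subclass", "custom"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"substrate panel missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        aliases = d.get("aliases")
        if aliases is None or (isinstance(aliases, float) and math.isnan(aliases)):
            aliases = ""
        derivation = d.get("derivation")
        if derivation is None or (isinstance(derivation, float) and math.isnan(derivation)):
            derivation = ""
        entries.append(
            SubstrateEntry(
                substrate_id=d["substrate_id"],
                sequence=d["sequence"],
                protease_class=d["protease_class"],
                subclass=d["subclass"],
                ph_opt_low=_parse_float(d.get("ph_opt_low")),
                ph_opt_high=_parse_float(d.get("ph_opt_high")),
                custom=str(d["custom"]).strip().lower() in {"yes", "true", "1"},
                derivation=str(derivation),
                aliases=tuple(a for a in str(aliases).split(";") if a),
            )
        )
    return SubstratePanel(entries)
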