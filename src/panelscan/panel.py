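"""Gene panels: symbols, families, protein lengths and transmembrane intervals.

A :class:`GenePanel` holds, per gene, the protein length ``L_g`` (residues)
and the 1-based inclusive transmembrane (TM) residue intervals whose total
covered length is ``L_TR``. Both lengths are measured in amino-acid residues,
matching the UniProt convention for TM annotations.

The shipped TRP-channel panel (:func:`trp_channel_panel`) contains the 28
transient-receptor potential channel genes in six families/sub-families
(TRPC, TRPM, TRPV, TRPA, TRPP, TRPML) with canonical human protein lengths.
The helix coordinates in that fixture are SYNTHETIC/approximate: each gene
carries the canonical six-TM channel architecture (11 TM for PKD1) placed
schematically within a plausible channel-domain span, not exact UniProt
residue intervals. Analyses that depend on real coordinates should load a
user-supplied TM-interval table via :meth:`GenePanel.from_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .containers import ConfigurationError, InputError

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[Interval] = []
    for a, b in ivs:
        if a > b:
            raise InputError(f"interval start {a} > end {b}")
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def covered_length(intervals: Iterable[Interval]) -> int:
    return sum(b - a + 1 for a, b in merge_intervals(intervals))


@dataclass(frozen=True)
class GenePanel:
    """Curated gene panel with per-gene TM annotation.

    ``genes`` is indexed by gene symbol with columns ``family`` and
    ``length`` (protein length in residues). ``tm_intervals`` maps each
    symbol to a tuple of merged, non-overlapping (start, end) residue
    intervals, 1-based inclusive; genes without TM annotation map to ().
    """

    genes: pd.DataFrame
    tm_intervals: Mapping[str, tuple[Interval, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes.index.has_duplicates:
            raise InputError("duplicate gene symbols in panel")
        if (self.genes["length"] <= 0).any():
            raise InputError("protein lengths must be positive")
        merged = {}
        for sym in self.genes.index:
            ivs = merge_intervals(self.tm_intervals.get(sym, ()))
            length = int(self.genes.at[sym, "length"])
            for a, b in ivs:
                if a < 1 or b > length:
                    raise ConfigurationError(
                        f"TM interval ({a},{b}) outside protein of length {length} for {sym}"
                    )
            merged[sym] = tuple(ivs)
        object.__setattr__(self, "tm_intervals", merged)

    # -- accessors ---------------------------------------------------------
    @property
    def symbols(self) -> list[str]:
        return list(self.genes.index)

    @property
    def families(self) -> list[str]:
        return sorted(self.genes["family"].unique())

    def length(self, symbol: str) -> int:
        return int(self.genes.at[symbol, "length"])

    def tm_length(self, symbol: str) -> int:
        return covered_length(self.tm_intervals.get(symbol, ()))

    def family(self, symbol: str) -> str:
        return str(self.genes.at[symbol, "family"])

    def in_tm(self, symbol: str, position: int) -> bool:
        return any(a <= position <= b for a, b in self.tm_intervals.get(symbol, ()))

    def subset(self, symbols: Sequence[str]) -> "GenePanel":
        return GenePanel(
            genes=self.genes.loc[list(symbols)].copy(),
            tm_intervals={s: self.tm_intervals.get(s, ()) for s in symbols},
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes.index

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tables(cls, panel_path: str | Path, tm_path: str | Path | None = None) -> "GenePanel":
        """Read a panel TSV (symbol, family, length) plus optional TM TSV (gene, start, end)."""
        genes = pd.read_csv(panel_path, sep="\t", comment="#").set_index("symbol")
        intervals: dict[str, list[Interval]] = {}
        if tm_path is not None:
            tm = pd.read_csv(tm_path, sep="\t", comment="#")
            for row in tm.itertuples(index=False):
                intervals.setdefault(str(row.gene), []).append((int(row.start), int(row.end)))
        return cls(genes=genes[["family", "length"]], tm_intervals={k: tuple(v) for k, v in intervals.items()})

    def to_tables(self, panel_path: str | Path, tm_path: str | Path) -> None:
        out = self.genes.reset_index().rename(columns={"index": "symbol"})
        if "symbol" not in out.columns:
            out = out.rename(columns={out.columns[0]: "symbol"})
        out["l_tm"] = [self.tm_length(s) for s in out["symbol"]]
        out.to_csv(panel_path, sep="\t", index=False, lineterminator="\n")
        rows = [
            {"gene": sym, "start": a, "end": b}
            for sym in self.symbols
            for a, b in self.tm_intervals.get(sym, ())
        ]
        pd.DataFrame(rows, columns=["gene", "start", "end"]).to_csv(
            tm_path, sep="\t", index=False, lineterminator="\n"
        )


def _spread_helices(span_start: int, span_end: int, n: int, helix_len: int = 21) -> tuple[Interval, ...]:
    """Place n non-overlapping helices of helix_len evenly within a span."""
    if n == 0:
        return ()
    block = (span_end - span_start + 1) // n
    if block < helix_len:
        raise ConfigurationError("span too short for requested helices")
    out = []
    for i in range(n):
        start = span_start + i * block + (block - helix_len) // 2
        out.append((start, start + helix_len - 1))
    return tuple(out)


# symbol: (family, canonical human protein length in residues, number of TM helices)
_TRP_PANEL: dict[str, tuple[str, int, int]] = {
    "TRPC1": ("TRPC", 793, 6),
    "TRPC3": ("TRPC", 848, 6),
    "TRPC4": ("TRPC", 977, 6),
    "TRPC5": ("TRPC", 973, 6),
    "TRPC6": ("TRPC", 931, 6),
    "TRPC7": ("TRPC", 862, 6),
    "TRPM1": ("TRPM", 1603, 6),
    "TRPM2": ("TRPM", 1503, 6),
    "TRPM3": ("TRPM", 1732, 6),
    "TRPM4": ("TRPM", 1214, 6),
    "TRPM5": ("TRPM", 1165, 6),
    "TRPM6": ("TRPM", 2022, 6),
    "TRPM7": ("TRPM", 1865, 6),
    "TRPM8": ("TRPM", 1104, 6),
    "TRPV1": ("TRPV", 839, 6),
    "TRPV2": ("TRPV", 764, 6),
    "TRPV3": ("TRPV", 790, 6),
    "TRPV4": ("TRPV", 871, 6),
    "TRPV5": ("TRPV", 729, 6),
    "TRPV6": ("TRPV", 725, 6),
    "TRPA1": ("TRPA", 1119, 6),
    "PKD1": ("TRPP", 4303, 11),
    "PKD2": ("TRPP", 968, 6),
    "PKD2L1": ("TRPP", 805, 6),
    "PKD2L2": ("TRPP", 624, 6),
    "MCOLN1": ("TRPML", 580, 6),
    "MCOLN2": ("TRPML", 566, 6),
    "MCOLN3": ("TRPML", 553, 6),
}


def trp_channel_panel() -> GenePanel:
    """The curated 28-gene TRP channel panel in six families.

    Protein lengths are canonical human UniProt lengths; TM helix
    coordinates are synthetic/approximate (schematic placement of the
    channel-domain helices), see module docstring.
    """
    records = []
    intervals: dict[str, tuple[Interval, ...]] = {}
    for sym, (family, length, n_tm) in _TRP_PANEL.items():
        records.append({"symbol": sym, "family": family, "length": length})
        span_start = int(round(0.50 * length))
        span_end = int(round(0.85 * length))
        intervals[sym] = _spread_helices(span_start, span_end, n_tm)
    genes = pd.DataFrame(records).set_index("symbol")
    return GenePanel(genes=genes, tm_intervals=intervals)
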