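"""Per-pair affinity records, category binning and table rendering."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .kinetics import format_sig

#: Default affinity bins (uM).  The boundaries are editorial conveniences
#: for summarising results: high-affinity complexes sit well below 1 uM,
#: detectable-but-weak ones above 100 uM.
DEFAULT_BINS = {"high": 1.0, "moderate": 100.0}

VALID_METHODS = ("stopped-flow", "FP-displacement", "none-detected")


@dataclass
class InteractionRecord:
    """One measured (or attempted) MDM2/p53TAD interaction."""

    mdm2_id: str
    p53tad_id: str
    method: str                      # one of VALID_METHODS
    K_D: float | None = None         # uM; None when nothing was detected
    K_D_err: float | None = None
    k_on: float | None = None        # 1/(uM s), kinetic records only
    k_on_err: float | None = None
    k_off: float | None = None       # 1/s
    k_off_err: float | None = None
    K_D_printed: str | None = None   # verbatim published string, if reproducing a table
    contemporary: bool = False       # tree-matched pair, rendered in bold
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}, got {self.method!r}")
        if self.method == "stopped-flow":
            if self.k_on is None or self.k_off is None:
                raise ValueError("stopped-flow records need k_on and k_off")
            if self.K_D is None:
                self.K_D = self.k_off / self.k_on
            elif not math.isclose(self.K_D, self.k_off / self.k_on, rel_tol=1e-12):
                raise ValueError("kinetic records must satisfy K_D == k_off / k_on")
        if self.method == "none-detected":
            if self.K_D is not None:
                raise ValueError("none-detected records carry no K_D")
        elif self.K_D is None or self.K_D <= 0:
            raise ValueError("measured records need a positive K_D")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mdm2_id, self.p53tad_id)


def classify_affinity(K_D: float | None, bins: dict[str, float] | None = None) -> str:
    """Bin a K_D (uM) into high / moderate / weak / none-detected.

    Defaults: high < 1 uM <= moderate <= 100 uM < weak; ``None`` means no
    interaction was detected by any method.
    """
    if K_D is None:
        return "none-detected"
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    bins = bins or DEFAULT_BINS
    if K_D < bins["high"]:
        return "high"
    if K_D <= bins["moderate"]:
        return "moderate"
    return "weak"


def build_affinity_table(
    records: list[InteractionRecord],
    bins: dict[str, float] | None = None,
    sig_figs: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Render interaction records into a publication-layout affinity table.

    One row per MDM2/p53TAD pair with formatted K_D, rate constants,
    affinity category and flags; ``sig_figs`` optionally pins the number of
    significant figures for particular pairs (default 2, the common table
    style for sub-micromolar values).
    """
    pairs = [r.pair for r in records]
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"duplicate pair ids: {dupes}")
    sig_figs = sig_figs or {}
    rows = []
    for r in records:
        n_sig = sig_figs.get(r.pair, 2)
        if r.K_D_printed is not None:
            kd_str = r.K_D_printed
        elif r.K_D is not None:
            kd_str = format_sig(r.K_D, n_sig)
        else:
            kd_str = "-"
        rows.append({
            "mdm2": f"**{r.mdm2_id}**" if r.contemporary else r.mdm2_id,
            "p53tad": f"**{r.p53tad_id}**" if r.contemporary else r.p53tad_id,
            "K_D (uM)": kd_str,
            "k_on (1/uM/s)": format_sig(r.k_on, 2) if r.k_on is not None else "",
            "k_off (1/s)": format_sig(r.k_off, 2) if r.k_off is not None else "",
            "method": r.method,
            "category": classify_affinity(r.K_D, bins),
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)


def table_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def table_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)


def motif_position(alignment_column: int, motif_start_column: int) -> int:
    """Map a 1-based alignment column onto human-p53 motif numbering (15-26).

    ``motif_start_column`` is the alignment column aligned with human p53
    residue 15; positions outside 15-26 are still returned (callers decide
    whether to display them)."""
    return 15 + (alignment_column - motif_start_column)


def swib_construct_length(start: int = 17, end: int = 125) -> int:
    """Number of residues in the reconstructed SWIB region (human 17-125)."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start + 1
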