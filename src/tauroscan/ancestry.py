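"""Window-based haplotype ancestry-origin painting.

Haplotypes of ``window_size`` consecutive SNPs are tallied in a taurine and an
indicine reference panel.  The probability that a window of an admixed animal
is of Bos taurus origin is the relative reference frequency

    b = p_bt / (p_bt + p_bi),

classified taurine when b > 0.6, indicine when b < 0.4 and undetermined in
between (boundary values inclusive).  Windows whose haplotype was never seen
in either panel, or that contain a missing genotype call, yield no call.
Everything in this module is deterministic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

TAURUS = "taurus"
INDICUS = "indicus"
UNDETERMINED = "undetermined"
NO_CALL = "no_call"

DEFAULT_WINDOW_SIZE = 10
DEFAULT_THRESHOLDS = (0.4, 0.6)


@dataclass(frozen=True)
class Window:
    """A run of consecutive markers treated as one multi-allelic unit."""

    index: int
    start: int          # marker index, inclusive
    stop: int           # marker index, exclusive
    chrom: str
    bp_start: int       # 1-based position of first marker
    bp_end: int         # 1-based position of last marker

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class WindowFrequencyTable:
    """Reference-panel frequencies of every haplotype observed in a window."""

    window: Window
    entries: dict  # haplotype string -> (p_bt, p_bi)

    def lookup(self, hap: str):
        return self.entries.get(hap)


@dataclass(frozen=True)
class AncestryCall:
    animal_id: str
    window: Window
    b: float | None
    cls: str


def build_windows(positions: np.ndarray, chrom: str = "X",
                  window_size: int = DEFAULT_WINDOW_SIZE) -> list[Window]:
    """Partition markers into disjoint consecutive windows of fixed size.

    Trailing markers that do not fill a window are dropped with a warning.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    positions = np.asarray(positions)
    n = len(positions)
    n_windows, remainder = divmod(n, window_size)
    if remainder:
        log.warning("dropping %d trailing marker(s) that do not fill a %d-SNP window",
                    remainder, window_size)
    if n_windows == 0:
        log.warning("fewer markers (%d) than window size (%d): no windows", n, window_size)
    return [
        Window(index=w, start=w * window_size, stop=(w + 1) * window_size,
               chrom=chrom,
               bp_start=int(positions[w * window_size]),
               bp_end=int(positions[(w + 1) * window_size - 1]))
        for w in range(n_windows)
    ]


def _haplotype_strings(counts: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Rows of a haploid count block as '0'/'1' strings; flags rows with missing."""
    has_missing = (counts == MISSING).any(axis=1)
    haps = ["".join("01"[c] for c in row) for row in counts]
    return haps, has_missing


def haplotype_frequencies(ref_taurus: GenotypeMatrix, ref_indicus: GenotypeMatrix,
                          window: Window) -> WindowFrequencyTable:
    """Relative frequency of every observed haplotype in each reference panel.

    Haplotypes containing a missing call are excluded from counting; a
    haplotype absent from one panel gets frequency 0 there.
    """
    tables = []
    for panel, name in ((ref_taurus, "taurine"), (ref_indicus, "indicine")):
        if not panel.is_haploid():
            raise ValueError(f"{name} reference panel must be haploid")
        block = panel.counts[:, window.start:window.stop]
        haps, missing = _haplotype_strings(block)
        kept = [h for h, miss in zip(haps, missing) if not miss]
        if not kept:
            raise ValueError(
                f"{name} panel empty after missing-data exclusion in window {window.index}")
        tally = Counter(kept)
        total = len(kept)
        tables.append({h: c / total for h, c in tally.items()})
    freq_t, freq_i = tables
    entries = {h: (freq_t.get(h, 0.0), freq_i.get(h, 0.0))
               for h in set(freq_t) | set(freq_i)}
    return WindowFrequencyTable(window=window, entries=entries)


def taurus_probability(p_bt: float, p_bi: float) -> float | None:
    """b = p_bt / (p_bt + p_bi); None when the haplotype is unseen in both panels."""
    if p_bt < 0 or p_bi < 0:
        raise ValueError("frequencies must be non-negative")
    total = p_bt + p_bi
    if total == 0:
        return None
    return p_bt / total


def classify(b: float | None, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Strict-inequality thresholding of b; boundary values are undetermined."""
    lo, hi = thresholds
    if b is None:
        return NO_CALL
    if b > hi:
        return TAURUS
    if b < lo:
        return INDICUS
    return UNDETERMINED


def paint_animal(animal_id: str, counts_row: np.ndarray, ploidy: int,
                 freq_tables: list[WindowFrequencyTable],
                 thresholds=DEFAULT_THRESHOLDS) -> list[AncestryCall]:
    """Ancestry calls for one haploid animal across all windows."""
    if ploidy != 1:
        raise ValueError("only haploid (male X) animals can be painted; "
                         "phasing of diploid genotypes is out of scope")
    calls = []
    for tab in freq_tables:
        w = tab.window
        block = counts_row[w.start:w.stop]
        if (block == MISSING).any():
            calls.append(AncestryCall(animal_id, w, None, NO_CALL))
            continue
        hap = "".join("01"[c] for c in block)
        entry = tab.lookup(hap)
        b = None if entry is None else taurus_probability(*entry)
        calls.append(AncestryCall(animal_id, w, b, classify(b, thresholds)))
    return calls


def paint_all(targets: GenotypeMatrix, ref_taurus: GenotypeMatrix,
              ref_indicus: GenotypeMatrix, window_size: int = DEFAULT_WINDOW_SIZE,
              thresholds=DEFAULT_THRESHOLDS) -> dict[str, list[AncestryCall]]:
    """Paint every target animal; returns animal_id -> list of AncestryCall."""
    windows = build_windows(targets.positions, targets.chrom, window_size)
    tables = [haplotype_frequencies(ref_taurus, ref_indicus, w) for w in windows]
    return {
        aid: paint_animal(aid, targets.counts[i], int(targets.ploidy[i]),
                          tables, thresholds)
        for i, aid in enumerate(targets.animal_ids)
    }


def taurine_proportion(calls, denominator: str = "classified_only") -> float | None:
    """Per-animal taurine fraction over windows.

    ``classified_only``: #taurus / (#taurus + #indicus).
    ``all_windows``: #taurus / #windows-with-a-call (undetermined counted in
    the denominator).  None (flagged) when the denominator is zero.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    n_taurus = sum(c.cls == TAURUS for c in calls)
    n_indicus = sum(c.cls == INDICUS for c in calls)
    n_called = sum(c.cls != NO_CALL for c in calls)
    if denominator == "classified_only":
        denom = n_taurus + n_indicus
    elif denominator == "all_windows":
        denom = n_called
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        log.warning("no classified windows for animal %s", calls[0].animal_id)
        return None
    return n_taurus / denom


def allele_group_profile(paintings: dict[str, list[AncestryCall]],
                         candidate_genotypes: dict[str, int],
                         window_range: tuple[int, int] | None = None):
    """Per-window taurine fraction for each candidate-SNP allele group.

    ``candidate_genotypes`` maps animal id to the hemizygous allele (0/1).
    Returns ``(profile, summary)``: ``profile`` has one row per window and one
    column per allele group holding the fraction of that group's animals whose
    window call is taurine (no-call animals excluded from the window's
    denominator); ``summary`` gives, per group over ``window_range`` (marker
    windows, half-open; default all), the mean/min/max of the per-window
    profile and the mean of per-animal taurine proportions.
    """
    groups: dict[int, list[str]] = {}
    for aid in paintings:
        if aid not in candidate_genotypes:
            raise ValueError(f"no candidate-SNP call for painted animal {aid}")
        groups.setdefault(int(candidate_genotypes[aid]), []).append(aid)
    for allele, members in groups.items():
        if not members:
            raise ValueError(f"allele group {allele} has no animals")

    any_calls = next(iter(paintings.values()))
    n_windows = len(any_calls)
    lo, hi = (0, n_windows) if window_range is None else window_range

    profile = {}
    for allele, members in sorted(groups.items()):
        fracs = np.full(n_windows, np.nan)
        for w in range(n_windows):
            statuses = [paintings[a][w].cls for a in members]
            called = [s for s in statuses if s != NO_CALL]
            if called:
                fracs[w] = sum(s == TAURUS for s in called) / len(called)
        profile[f"allele_{allele}"] = fracs
    profile_df = pd.DataFrame(profile, index=pd.RangeIndex(n_windows, name="window"))

    rows = []
    for allele, members in sorted(groups.items()):
        col = profile_df[f"allele_{allele}"].iloc[lo:hi].dropna()
        per_animal = [taurine_proportion(paintings[a][lo:hi], "all_windows")
                      for a in members]
        per_animal = [x for x in per_animal if x is not None]
        rows.append({
            "allele": allele,
            "n_animals": len(members),
            "window_mean": float(col.mean()),
            "window_min": float(col.min()),
            "window_max": float(col.max()),
            "animal_mean": float(np.mean(per_animal)) if per_animal else np.nan,
        })
    summary = pd.DataFrame(rows).set_index("allele")
    return profile_df, summary
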