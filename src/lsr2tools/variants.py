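"""Design GC-raised variants of an AT-rich binding-site sequence.

Binding-affinity experiments on silencer target sites compare a wild-type
AT-rich probe against variants of increasing GC content, raised either by
specifically disrupting the AT-rich cores (5-of-6 A/T hexamers) or by
raising overall GC while leaving the cores intact. This module reproduces
that design logic: only A/T→G/C substitutions are made, the achieved GC is
within ±0.5 percentage points of the requested target, and the two modes
differ in which positions are eligible:

* ``disrupt_cores`` — substitutions are targeted at positions covered by
  the most qualifying core hexamers (ties broken leftmost) until no core
  remains, then spent on remaining A/T positions at random;
* ``spare_cores`` — substitutions are restricted to A/T positions covered
  by no qualifying core hexamer, so every core survives by construction.

The replacement letter (G or C) is a seeded coin flip; the whole design is
deterministic under (sequence, spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence import NucSequence, ScanConfig, count_at_cores, gc_content

__all__ = ["VariantSpec", "ChangeReport", "raise_gc"]

GC_TOLERANCE = 0.005


@dataclass(frozen=True)
class VariantSpec:
    """Target and constraints for a GC-raising design."""

    target_gc: float
    mode: str = "disrupt_cores"
    protected_intervals: tuple[tuple[int, int], ...] = ()
    seed: int = 0
    scan: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.target_gc <= 1):
            raise ValueError("target_gc must lie in [0, 1]")
        if self.mode not in {"disrupt_cores", "spare_cores"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ChangeReport:
    """Positions changed (1-based), with composition before/after."""

    positions: tuple[int, ...]
    replacements: tuple[str, ...]
    gc_before: float
    gc_after: float
    cores_before: tuple[int, int]
    cores_after: tuple[int, int]

    @property
    def n_changes(self) -> int:
        return len(self.positions)


def _core_starts(residues: str, cfg: ScanConfig) -> list[int]:
    """0-based starts of qualifying core hexamers."""
    starts = []
    k, m = cfg.core_len, cfg.core_min_at
    for i in range(len(residues) - k + 1):
        window = residues[i : i + k]
        if sum(window.count(b) for b in "AT") >= m:
            starts.append(i)
    return starts


def _coverage(residues: str, cfg: ScanConfig) -> np.ndarray:
    """Per-position count of qualifying core hexamers covering it."""
    cov = np.zeros(len(residues), dtype=int)
    for s in _core_starts(residues, cfg):
        cov[s : s + cfg.core_len] += 1
    return cov


def raise_gc(seq: NucSequence | str, spec: VariantSpec) -> tuple[NucSequence, ChangeReport]:
    """Raise a sequence's GC content to ``spec.target_gc`` by A/T→G/C substitution.

    Raises ``ValueError`` when the target is below the current GC content
    (lowering is out of scope), when it cannot be hit within ±0.5
    percentage points given the protected intervals and mode constraints,
    or when a protected interval lies outside the sequence.
    """
    if isinstance(seq, str):
        seq = NucSequence("variant_input", seq)
    residues = list(seq.residues)
    n_eff = sum(1 for b in residues if b != "N")
    if n_eff == 0:
        raise ValueError("cannot design a variant of an empty or all-N sequence")
    for lo, hi in spec.protected_intervals:
        if not (1 <= lo <= hi <= len(residues)):
            raise ValueError(f"protected interval ({lo}, {hi}) outside the sequence")

    protected = np.zeros(len(residues), dtype=bool)
    for lo, hi in spec.protected_intervals:
        protected[lo - 1 : hi] = True

    gc_before = gc_content(seq)
    cores_before = count_at_cores(seq, spec.scan)
    gc_count = sum(1 for b in residues if b in "GC")
    budget = round(spec.target_gc * n_eff) - gc_count
    if budget < 0:
        raise ValueError(
            f"target GC {spec.target_gc:.3f} is below the current {gc_before:.3f}; "
            "only raising GC is supported"
        )
    achieved = (gc_count + budget) / n_eff
    if abs(achieved - spec.target_gc) > GC_TOLERANCE:
        raise ValueError(
            f"target {spec.target_gc:.4f} not achievable within ±{GC_TOLERANCE}: "
            f"nearest attainable GC is {achieved:.4f}"
        )

    rng = np.random.default_rng(spec.seed)
    positions: list[int] = []  # 0-based
    replacements: list[str] = []

    def substitute(pos: int) -> None:
        letter = "G" if rng.integers(2) == 0 else "C"
        residues[pos] = letter
        positions.append(pos)
        replacements.append(letter)

    def eligible_mask() -> np.ndarray:
        is_at = np.array([b in "AT" for b in residues])
        return is_at & ~protected

    remaining = budget
    if spec.mode == "disrupt_cores":
        # Greedy: hit the position covered by the most surviving cores.
        while remaining > 0:
            cov = _coverage("".join(residues), spec.scan)
            elig = eligible_mask()
            cov[~elig] = 0
            best = int(cov.argmax())
            if cov[best] == 0:
                break  # no qualifying core touches a mutable A/T position
            substitute(best)
            remaining -= 1
    else:  # spare_cores: never touch a position under any qualifying core
        cov = _coverage("".join(residues), spec.scan)
        elig = np.flatnonzero(eligible_mask() & (cov == 0))
        if remaining > elig.size:
            raise ValueError(
                f"spare_cores mode needs {remaining} substitutions but only "
                f"{elig.size} A/T positions lie outside cores and protection"
            )
        for pos in rng.choice(elig, size=remaining, replace=False):
            substitute(int(pos))
        remaining = 0

    if remaining > 0:  # disrupt mode with cores exhausted: spend the rest anywhere
        elig = np.flatnonzero(eligible_mask())
        if remaining > elig.size:
            raise ValueError(
                f"need {remaining} more substitutions but only {elig.size} "
                "mutable A/T positions remain"
            )
        for pos in rng.choice(elig, size=remaining, replace=False):
            substitute(int(pos))

    variant = NucSequence(id=f"{seq.id}_gc{round(spec.target_gc * 100)}", residues="".join(residues))
    order = np.argsort(positions)
    report = ChangeReport(
        positions=tuple(int(positions[i]) + 1 for i in order),
        replacements=tuple(replacements[i] for i in order),
        gc_before=gc_before,
        gc_after=gc_content(variant),
        cores_before=cores_before,
        cores_after=count_at_cores(variant, spec.scan),
    )
    return variant, report
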