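"""Run-level configuration shared by every stage of the pipeline.

The defaults encode the screen design this package targets: 96-well
plates whose column 12 carries negative (non-targeting, siNT) and
positive (lethal) transfection controls in alternating rows, a -3*sigma
d threshold for differential hits in the primary screen, a -2*sigma
threshold in confirmation runs, and a 20 %NT cutoff for oligos lethal
to both cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ScreenError

#: role names allowed in the control-column pattern
_CONTROL_ROLES = ("control_nt", "control_pos")


@dataclass(frozen=True)
class ScreenConfig:
    """Analysis parameters for a screening run.

    Parameters
    ----------
    k_screen:
        Multiple of sigma below the mean d defining differential hits in
        the primary screen (threshold = mu - k_screen * sigma).
    k_confirm:
        Sigma multiple used when re-calling phenotypes on a confirmation
        run.
    lethal_cutoff:
        %NT at or below which an oligo counts as lethal in a cell line;
        lethal in both lines makes a "lethal_both" call.
    control_column:
        Plate column reserved for controls (1-based).
    control_pattern:
        Role sequence repeated down the control column starting at row A.
        The default alternates non-targeting and positive controls,
        giving 4 NT + 4 positive wells on an 8-row plate.
    nt_wells_used:
        If set, only the first ``nt_wells_used`` NT wells (row order) of
        each plate enter the NT average; ``None`` uses all of them.
    rounding_digits:
        Decimal places for reported percentages (round-half-even).
    min_confirm_stats_n:
        Minimum confirmation-run size for fitting its own d distribution;
        smaller runs fall back to the screening-run statistics.
    """

    k_screen: float = 3.0
    k_confirm: float = 2.0
    lethal_cutoff: float = 20.0
    control_column: int = 12
    control_pattern: tuple[str, ...] = ("control_nt", "control_pos")
    nt_wells_used: int | None = None
    rounding_digits: int = 2
    min_confirm_stats_n: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lethal_cutoff < 100.0):
            raise ScreenError(
                f"lethal_cutoff must lie in (0, 100), got {self.lethal_cutoff}"
            )
        if self.k_screen <= 0 or self.k_confirm <= 0:
            raise ScreenError("sigma multiples k_screen/k_confirm must be > 0")
        if not 1 <= self.control_column <= 12:
            raise ScreenError(f"control_column out of range: {self.control_column}")
        if not self.control_pattern:
            raise ScreenError("control_pattern must be non-empty")
        for role in self.control_pattern:
            if role not in _CONTROL_ROLES:
                raise ScreenError(f"unknown control role in pattern: {role!r}")
        if "control_nt" not in self.control_pattern:
            raise ScreenError("control_pattern must contain at least one control_nt")
        if self.nt_wells_used is not None and self.nt_wells_used < 1:
            raise ScreenError("nt_wells_used must be >= 1 when set")

    def control_roles(self, n_rows: int = 8) -> tuple[str, ...]:
        """Role of each control-column well, rows A.. in order."""
        pat = self.control_pattern
        return tuple(pat[i % len(pat)] for i in range(n_rows))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        """Load a config from a YAML mapping; absent keys keep defaults."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ScreenError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ScreenError(f"unknown config keys: {sorted(unknown)}")
        if "control_pattern" in data:
            data["control_pattern"] = tuple(data["control_pattern"])
        return cls(**data)

    def with_(self, **kwargs) -> "ScreenConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
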