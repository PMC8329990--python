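"""Tetraspanin-capture chip (SP-IRIS) quantification.

Each chip spot captures EVs through one immobilized antibody (anti-CD63,
-CD81, -CD9, or an IgG isotype control); captured vesicles are immunolabelled
with CF647 anti-tetraspanin antibodies (total EV channel) and a CF555
anti-GFP antibody (cargo channel).  The headline statistic is

    %GFP+ = 100 x (CF555-positive events) / (CF647-positive events),

the literal count ratio; a colocalized-only variant (CF555+ AND CF647+
numerator) is available behind a flag.  GFP MFI is the mean CF555 intensity
over all events on a spot.  Counts on the isotype spot measure nonspecific
adsorption and are subtracted, with a flag when they exceed 10% of any
tetraspanin spot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from evcq._errors import ConfigError, EvcqError

__all__ = [
    "ChipResult",
    "size_window_filter",
    "percent_colocalized",
    "spot_mfi",
    "isotype_background",
]


@dataclass(frozen=True)
class ChipResult:
    """Per-capture-spot quantification."""

    capture_antibody: str
    n_events: int
    n_cf647_pos: int
    n_cf555_pos: int
    percent_gfp_pos: float
    mfi_cf555: float
    exceeds_100: bool = False


def size_window_filter(
    events: pd.DataFrame, min_nm: float = 50.0, max_nm: float = 200.0
) -> pd.DataFrame:
    """Keep events with diameter in the closed window [min_nm, max_nm].

    If the table has no diameter column the filter is the identity (the
    instrument did not size this acquisition) — a warning is the caller's
    concern, not an error.
    """
    if min_nm <= 0 or max_nm <= min_nm:
        raise ConfigError("need 0 < min_nm < max_nm")
    if "diameter_nm" not in events.columns or len(events) == 0:
        return events
    d = events["diameter_nm"].to_numpy(dtype=float)
    keep = (d >= min_nm) & (d <= max_nm)
    return events.loc[keep].reset_index(drop=True)


def percent_colocalized(
    events: pd.DataFrame,
    cf647_gate_adu: float,
    cf555_gate_adu: float,
    capture_antibody: str = "",
    colocalized_only: bool = False,
) -> ChipResult:
    """%GFP+ = 100 x CF555-positive / CF647-positive on one capture spot.

    ``colocalized_only=True`` restricts the numerator to events positive in
    BOTH channels, which caps the ratio at 100; the default literal ratio can
    exceed 100 when more CF555+ than CF647+ events exist — such results are
    reported and flagged, not clipped.
    """
    if cf647_gate_adu < 0 or cf555_gate_adu < 0:
        raise ConfigError("gates must be >= 0")
    cf647 = events["cf647_adu"].to_numpy(dtype=float) if len(events) else np.empty(0)
    cf555 = events["cf555_adu"].to_numpy(dtype=float) if len(events) else np.empty(0)
    pos647 = cf647 > cf647_gate_adu
    pos555 = cf555 > cf555_gate_adu
    n647 = int(pos647.sum())
    if n647 == 0:
        raise EvcqError("no captured vesicles: zero CF647-positive events")
    numer = pos555 & pos647 if colocalized_only else pos555
    n555 = int(numer.sum())
    pct = 100.0 * n555 / n647
    return ChipResult(
        capture_antibody=capture_antibody,
        n_events=int(len(events)),
        n_cf647_pos=n647,
        n_cf555_pos=n555,
        percent_gfp_pos=pct,
        mfi_cf555=float(cf555.mean()) if len(events) else float("nan"),
        exceeds_100=pct > 100.0,
    )


def spot_mfi(events: pd.DataFrame, channel: str = "cf555_adu") -> float:
    """Arithmetic mean of a channel over all events on the spot."""
    if len(events) == 0:
        raise EvcqError("empty spot: MFI undefined")
    if channel not in events.columns:
        raise ConfigError(f"events table lacks channel column {channel!r}")
    return float(events[channel].mean())


def isotype_background(
    sample_counts: Mapping[str, int],
    igg_count: int,
    contamination_fraction: float = 0.1,
) -> tuple[dict[str, int], bool]:
    """Isotype-corrected per-spot counts plus a contamination flag.

    Corrected count = max(0, spot count - IgG count).  The flag is raised
    when the IgG count exceeds ``contamination_fraction`` (default 10%) of
    any tetraspanin spot count, signalling that nonspecific binding is not
    negligible relative to specific capture.
    """
    if igg_count < 0:
        raise ConfigError("IgG count must be >= 0")
    corrected = {m: max(0, int(n) - int(igg_count)) for m, n in sample_counts.items()}
    flag = any(
        igg_count > contamination_fraction * n for n in sample_counts.values()
    )
    return corrected, flag
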