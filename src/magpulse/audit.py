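"""Empirical audit of magnetic pulsers used in orientation experiments.

Earlier pulse studies used devices whose control condition did not reproduce
the treatment's induced electric field: a double-wrapped solenoid run in
antiparallel mode cancels (most of) the magnetic field but leaks a scaled-down
pulse, so its onset dB/dt — and hence the Faraday spike — is a small fraction
of the treatment's.  A truncated-discharge sham, by contrast, shares the
treatment onset exactly.  This module represents devices empirically (peak
fields and rise specs, as published or bench-measured, not circuit models)
and flags per device whether the control mode is an adequate electric-field
control and whether its field stays below the magnetite no-effect threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .errors import InvalidParameterError
from .sham import ShamCriteria, SwitchingModel

#: How the control/sham field relates to the treatment pulse.
#: ``truncated_sham``: same discharge cut short (onset dB/dt ratio 1);
#: ``scaled_leak``: same shape scaled down (onset ratio = peak leak ratio);
#: ``none``: no control pulse at all (onset ratio 0).
CONTROL_MODES = ("truncated_sham", "scaled_leak", "none")


@dataclass(frozen=True)
class DeviceRecord:
    """One pulser, described by bench measurements.

    ``rise_fraction`` of the treatment peak is reached within ``rise_time``
    seconds; ``b_peak_control`` is the control-mode field (0 if the device
    has no control pulse).  Fields in mT.
    """

    name: str
    b_peak_treat: float
    rise_fraction: float
    rise_time: float
    b_peak_control: float = 0.0
    control_mode: str = "none"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.b_peak_treat <= 0:
            raise InvalidParameterError("b_peak_treat must be > 0")
        if not (0 < self.rise_fraction <= 1):
            raise InvalidParameterError("rise_fraction must be in (0, 1]")
        if self.rise_time <= 0:
            raise InvalidParameterError("rise_time must be > 0")
        if not (0 <= self.b_peak_control <= self.b_peak_treat):
            raise InvalidParameterError(
                "need 0 <= b_peak_control <= b_peak_treat")
        if self.control_mode not in CONTROL_MODES:
            raise InvalidParameterError(
                f"control_mode must be one of {CONTROL_MODES}")


def rate_of_change_estimate(b_peak: float, fraction: float,
                            t_rise: float) -> float:
    """Average onset field rate (T/ms) from a fraction-of-peak rise spec.

    ``b_peak`` in mT, ``t_rise`` in seconds; returns
    (fraction * b_peak) / t_rise converted to T per ms.
    """
    if not fraction > 0 or fraction > 1:
        raise InvalidParameterError("fraction must be in (0, 1]")
    if t_rise <= 0:
        raise InvalidParameterError("t_rise must be > 0")
    if b_peak < 0:
        raise InvalidParameterError("b_peak must be >= 0")
    return (fraction * b_peak * 1e-3) / (t_rise * 1e3)


def audit_device(record: DeviceRecord,
                 criteria: ShamCriteria = ShamCriteria(),
                 switching: SwitchingModel = SwitchingModel()) -> dict:
    """Audit one device: leak ratio, onset dB/dt ratio, adequacy flags.

    An adequate electric-field control needs a control-to-treatment onset
    dB/dt ratio of ~1 (within ``criteria.onset_rate_tolerance``); a scaled
    leak of a few percent fails.  The control field must also stay below the
    magnetite no-effect threshold.
    """
    leak_ratio = record.b_peak_control / record.b_peak_treat
    if record.control_mode == "truncated_sham":
        onset_ratio = 1.0
    elif record.control_mode == "scaled_leak":
        onset_ratio = leak_ratio
    else:
        onset_ratio = 0.0
    return {
        "name": record.name,
        "b_peak_treat_mt": record.b_peak_treat,
        "b_peak_control_mt": record.b_peak_control,
        "onset_rate_t_per_ms": rate_of_change_estimate(
            record.b_peak_treat, record.rise_fraction, record.rise_time),
        "leak_ratio": leak_ratio,
        "onset_dbdt_ratio": onset_ratio,
        "adequate_efield_control": bool(
            abs(onset_ratio - 1.0) <= criteria.onset_rate_tolerance),
        "control_below_no_effect": bool(
            record.b_peak_control < switching.b_no_effect),
        "notes": record.notes,
    }


def audit_table(records: list[DeviceRecord],
                criteria: ShamCriteria = ShamCriteria(),
                switching: SwitchingModel = SwitchingModel()) -> pd.DataFrame:
    """Name-sorted audit table over several devices.

    Duplicate names are suffixed ``_2``, ``_3``, ... in input order so rows
    stay uniquely addressable.
    """
    if not records:
        raise InvalidParameterError("need at least one device record")
    rows = [audit_device(r, criteria, switching) for r in records]
    seen: dict[str, int] = {}
    for row in rows:
        n = seen.get(row["name"], 0) + 1
        seen[row["name"]] = n
        if n > 1:
            row["name"] = f"{row['name']}_{n}"
    df = pd.DataFrame(rows).sort_values("name", kind="stable")
    return df.reset_index(drop=True)


def builtin_devices() -> list[DeviceRecord]:
    """Device fixtures shipped with the package (published/bench values)."""
    text = resources.files("magpulse").joinpath("data/devices.yaml").read_text()
    raw = yaml.safe_load(text)
    return [DeviceRecord(**entry) for entry in raw["devices"]]
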