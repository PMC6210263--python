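"""Independent brute-force oracles the fast implementations are checked against."""

from __future__ import annotations

from workrisk.exposure import HOURS_PER_YEAR, ExposureProfile


def hour_grid_exposure_concentration(profile: ExposureProfile) -> float:
    """Accumulate CA over every exposed hour of a simulated year, then ÷ 8760.

    Requires integer ET (h/day) and EF (day/year) so each exposed hour is a
    literal grid cell; deliberately loops instead of multiplying.
    """
    total = 0.0
    for stay in profile.stays:
        et, ef = int(stay.et), int(stay.ef)
        assert et == stay.et and ef == stay.ef, "oracle needs integer schedules"
        for _day in range(ef):
            for _hour in range(et):
                total += stay.ca
    return total / HOURS_PER_YEAR
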