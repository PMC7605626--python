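"""Small shared financial helpers."""

from __future__ import annotations


def annuity_factor(rate: float, years: int) -> float:
    """Present value of 1 per year paid in years 1..years at `rate`."""
    if rate < 0:
        raise ValueError(f"discount rate must be non-negative, got {rate}")
    if years < 0:
        raise ValueError(f"years must be non-negative, got {years}")
    if rate == 0:
        return float(years)
    return (1.0 - (1.0 + rate) ** -years) / rate
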