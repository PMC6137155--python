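"""Small shared construction helpers for the test suite."""

from stdgem.quantify import PeakRecord, quantify_peaks


def profile_from_abs(abs_map, compound="c1", I0=200.0):
    """Quantified profile whose absolute STD percentages equal abs_map."""
    records = [
        PeakRecord(compound, label, 7.5, I0, I0 * (1 - pct / 100.0), 2.94)
        for label, pct in abs_map.items()
    ]
    return quantify_peaks(records)
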