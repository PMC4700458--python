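"""Shared column names and rendering constants."""

PARAM_COLUMNS = ("apd30_ms", "apd80_ms", "triangulation_ms", "fractional_repolarization")

#: iso-contour spacing for spatial maps: 10 ms for durations, 0.05 for
#: fractional repolarization
CONTOUR_SPACING = {
    "apd30_ms": 10.0,
    "apd80_ms": 10.0,
    "triangulation_ms": 10.0,
    "fractional_repolarization": 0.05,
}
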