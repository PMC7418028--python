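"""Bundled reference measurements used in examples and validation.

Nine natural and synthetic carbonates spanning near-equilibrium
precipitates (a vein calcite grown over millennia at constant 33.7 °C, a
cave pool carbonate, a cryogenic cave carbonate) and kinetically biased
ones (a laboratory-grown speleothem analogue, a stalagmite, warm- and
cold-water scleractinian corals, a modern brachiopod), plus a Cretaceous
belemnite of unknown growth temperature.  Values are session-corrected
sample means (‰, CDES90) with 2 SE and replicate counts; growth
temperatures are the independently known formation temperatures with their
2 SE.  The ``process`` column names the kinetic regime expected from the
formation environment (degassing for speleothems, absorption for
biomineralisers) and selects the projection slope.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["reference_carbonates"]

_ROWS = [
    # sample_id, type, n, d47, se47_2, d48, se48_2, growth_T_C, growth_T_2se, process
    ("DHC2-8", "vein calcite", 5, 0.575, 0.006, 0.226, 0.023, 33.7, 0.8, "none"),
    ("Obi 87-i", "pool carbonate", 7, 0.660, 0.007, 0.267, 0.024, 4.0, 3.0, "none"),
    ("MSK 2b", "cryogenic cave carbonate", 8, 0.674, 0.005, 0.271, 0.029, 0.0, 0.5, "none"),
    ("MHD1", "synthetic speleothem", 6, 0.547, 0.008, 0.254, 0.027, 30.7, 0.3, "degassing"),
    ("SPA121-02", "stalagmite", 6, 0.644, 0.009, 0.290, 0.025, 0.0, 2.0, "degassing"),
    ("PC1_2005", "warm-water coral", 10, 0.626, 0.005, 0.136, 0.022, 29.3, 1.0, "absorption"),
    ("JR", "cold-water coral", 10, 0.719, 0.005, 0.189, 0.030, 7.2, 1.0, "absorption"),
    ("Mv143-b", "brachiopod", 9, 0.675, 0.004, 0.250, 0.015, 11.4, 1.7, "absorption"),
    ("66-4.65", "belemnite", 9, 0.610, 0.005, 0.251, 0.021, None, None, "none"),
]


def reference_carbonates() -> pd.DataFrame:
    """The bundled carbonate reference set as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "sample_id", "type", "n",
            "d47", "se47_2", "d48", "se48_2",
            "growth_temperature_C", "growth_temperature_2se", "process",
        ],
    )
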