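"""Packaged example data."""

from __future__ import annotations

from importlib import resources

from .io import Dataset, read_ad_csv

__all__ = ["load_oncology"]


def load_oncology() -> Dataset:
    """Nine late-stage oncology trials of one compound (aggregate data).

    One row per arm; follow-up durations are in months.  The treatment arm
    of each trial is the one containing the compound of interest (possibly
    in combination with other therapies); indications differ across trials,
    which makes the control arms markedly more heterogeneous than the
    treatment arms — analyses of these data therefore anchor the hierarchy
    on the treatment arm.  No historical control trials exist.
    """
    with resources.as_file(resources.files("aemeta").joinpath("data/oncology.csv")) as p:
        return read_ad_csv(p, time_unit="months")
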