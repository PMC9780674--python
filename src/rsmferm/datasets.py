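"""Packaged example data: the published three-stage medium-optimization study.

These are the printed inputs of a medium-optimization experiment for
mycelial soluble protein of *Ophiocordyceps sinensis*: a 12-run, 6-factor
Plackett-Burman screen, a 5-step steepest-ascent path, and a 17-run
3-factor Box-Behnken design with 5 center replicates.  Responses are
per-run means (+/- SE of triplicates) in percent protein.
"""

from __future__ import annotations

from importlib import resources

from .ascent import AscentPath
from .design import DesignMatrix, FactorDef, ResponseSet

__all__ = [
    "pb_factors",
    "pb_screen",
    "ascent_path",
    "bbd_factors",
    "bbd_experiment",
    "verification_observation",
]


def _data(name: str):
    return resources.files("rsmferm.data") / name


def pb_factors() -> list[FactorDef]:
    """The six screened medium components with their -1/+1 actual levels."""
    from .io import read_factors

    return read_factors(_data("pb_factors.json"))


def pb_screen() -> tuple[DesignMatrix, ResponseSet]:
    """12-run Plackett-Burman design and mean protein responses."""
    from .io import read_design, read_response

    design = read_design(_data("pb_design.csv"), factors=pb_factors())
    responses = read_response(_data("pb_response.csv"))
    return design, responses


def ascent_path() -> AscentPath:
    """5-step steepest-ascent grid with observed responses.

    Beef broth, peptone and glucose move; yeast extract, KH2PO4 and MgSO4
    are held at 0.15, 0.20 and 0.02 %.
    """
    from .io import _load_ascent_csv

    return _load_ascent_csv(_data("ascent_path.csv"))


def bbd_factors() -> list[FactorDef]:
    """The three surface factors centered at the winning ascent step."""
    from .io import read_factors

    return read_factors(_data("bbd_factors.json"))


def bbd_experiment() -> tuple[DesignMatrix, ResponseSet]:
    """17-run Box-Behnken design (5 center replicates) and responses."""
    from .io import read_design, read_response

    design = read_design(_data("bbd_design.csv"), factors=bbd_factors())
    responses = read_response(_data("bbd_response.csv"))
    return design, responses


def verification_observation() -> dict:
    """Replicate verification run at the reported optimum settings."""
    return {"observed_mean": 2.03, "observed_se": 0.01}
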