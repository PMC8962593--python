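import numpy as np
import pytest

from pathwayopt.defaults import default_hill, default_landscape, default_library
from pathwayopt.preprocess import build_design_matrix, filter_dataset, scale_from_library
from pathwayopt.io import colonies_to_records
from pathwayopt.simulate import select_range_covering_subset, simulate_screen
from pathwayopt.space import CdsVariant, LibrarySpec, OperonSpec, PromoterPart

STEPS = ("TAL", "4CL", "CHS", "CHI")
CDS = {
    "TAL": ("RgTAL", "FjTAL"),
    "4CL": ("Pc4CL", "At4CL"),
    "CHS": ("GhCHS", "PhCHS"),
    "CHI": ("MsCHI", "PhCHI"),
}


def make_library(n_promoters=10, tif_lo=1.0, tif_hi=400.0, steps=STEPS):
    """Library with a shared geometric promoter series and 2 isozymes/step."""
    proms = tuple(
        PromoterPart(f"P_B{i + 1}", float(t))
        for i, t in enumerate(np.geomspace(tif_lo, tif_hi, n_promoters))
    )
    return LibrarySpec(
        tuple(
            OperonSpec(s, proms, tuple(CdsVariant(c, s) for c in CDS[s]))
            for s in steps
        )
    )


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_library():
    return make_library(n_promoters=3)


@pytest.fixture(scope="session")
def scale(library):
    return scale_from_library(library)


@pytest.fixture(scope="session")
def screen(library):
    """A deterministic 190-colony simulated screen under default conditions."""
    return simulate_screen(
        library, default_landscape(), default_hill(), 190, seed=11
    )


@pytest.fixture(scope="session")
def selected_records(screen):
    return colonies_to_records(select_range_covering_subset(screen, 35))


@pytest.fixture(scope="session")
def modelling_data(selected_records, library, scale):
    """Filtered records, design matrix and titer vector for model tests."""
    filtered, _report = filter_dataset(selected_records)
    design = build_design_matrix(filtered, scale, library)
    titer = np.array([r.titer for r in filtered])
    return filtered, design, titer
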