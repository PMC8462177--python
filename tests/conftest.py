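import numpy as np
import pandas as pd
import pytest

from edelweiss import synthetic
from edelweiss.geodata import GridSpec, Raster


@pytest.fixture(scope="session")
def truth():
    return synthetic.SyntheticTruth(seed=5)


@pytest.fixture(scope="session")
def landscape(truth):
    return synthetic.make_landscape(truth, seed=5)


@pytest.fixture(scope="session")
def trails(truth, landscape):
    return synthetic.make_trails(truth, landscape, seed=6)


@pytest.fixture(scope="session")
def favorability(truth, landscape):
    return synthetic.true_occupancy(truth, landscape)


@pytest.fixture(scope="session")
def demo_tables(truth, favorability, trails):
    """Default noisy demography tables plus the generative record."""
    return synthetic.make_demography(truth, favorability, trails, seed=7, noise=True)


@pytest.fixture(scope="session")
def demo_tables_noise_off(truth, favorability, trails):
    return synthetic.make_demography(truth, favorability, trails, seed=7, noise=False)


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=5, n_cols=6, x_origin=0.0, y_origin=50.0, cell_size=10.0)


@pytest.fixture
def random_raster(small_spec):
    rng = np.random.default_rng(3)
    return Raster(small_spec, rng.uniform(0, 100, small_spec.shape), "z")


@pytest.fixture
def occ_dataset(truth, landscape):
    """Deduped presences + 10x pseudo-absences with predictor values."""
    import warnings

    from edelweiss import geodata, occurrence

    preds = ["temperature", "precipitation", "tri"]
    occ = synthetic.sample_occurrences(truth, landscape, 424, seed=12)
    pts = geodata.assign_cells(occ, landscape["tri"].spec)
    ded = geodata.dedupe_presences(pts)
    for name in preds:
        ded = geodata.extract_at_points(landscape[name], ded, column=name)
    ded = ded.dropna(subset=preds)
    env = occurrence.fit_envelope(ded, preds, q=0.95)
    spec = landscape["tri"].spec
    rr, cc = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij")
    cx, cy = spec.cell_center(rr.ravel(), cc.ravel())
    cand = pd.DataFrame({"x": cx, "y": cy, "row": rr.ravel(), "col": cc.ravel()})
    for name in preds:
        cand[name] = landscape[name].values[cand["row"], cand["col"]]
    cand = cand.dropna(subset=preds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = occurrence.sample_pseudo_absences(
            env, cand, n_presence=len(ded), ratio=10, seed=13,
            presence_cells=set(zip(ded["row"], ded["col"])),
        )
    ded = ded.copy()
    ded["label"] = "presence"
    data = pd.concat([ded, pa], ignore_index=True)[["x", "y", "row", "col", "label", *preds]]
    return data, env, preds
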