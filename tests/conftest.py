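import numpy as np
import pytest

from specindexnet import synthetic
from specindexnet.preprocess import SpectralDataset, SpectralSample

np.seterr(over="ignore", invalid="ignore", divide="ignore")


@pytest.fixture(scope="session")
def small_dataset():
    """200 labeled synthetic samples shared by cheap tests."""
    return synthetic.generate_dataset(200, seed=7)


@pytest.fixture()
def toy_sample():
    wl = np.linspace(400, 1000, 204)
    rng = np.random.default_rng(0)
    return SpectralSample("toy", wl, np.clip(0.3 + 0.1 * rng.standard_normal(204), 0, 1))


@pytest.fixture()
def spectra_csv(tmp_path):
    """3-row spectra CSV + traits CSV with one sample missing a trait row."""
    wl = np.linspace(400, 1000, 7)
    rng = np.random.default_rng(1)
    lines = ["sample_id," + ",".join(f"R_{w:g}" for w in wl)]
    for sid in ("a", "b", "c"):
        vals = rng.uniform(0.05, 0.9, size=wl.size)
        lines.append(sid + "," + ",".join(f"{v:.6f}" for v in vals))
    spath = tmp_path / "spectra.csv"
    spath.write_text("\n".join(lines) + "\n")
    tpath = tmp_path / "traits.csv"
    tpath.write_text("sample_id,vcmax,jmax\na,50.0,96.5\nb,70.0,135.1\n")
    return spath, tpath
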