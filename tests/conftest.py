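import numpy as np
import pytest

from synscreen.doseresponse import HillFit
from synscreen.grids import DoseMatrix


def symmetric_fit(ec50: float, h: float = 1.0, e0: float = 1.0,
                  einf: float = 0.0) -> HillFit:
    return HillFit(e0=e0, einf=einf, ec50=ec50, h=h, rss=0.0, n_points=0,
                   converged=True, identifiable=True)


def matrix_from_surface(fit_a: HillFit, fit_b: HillFit, top_a: float,
                        top_b: float, combo_fn=None, n: int = 6,
                        n_replicates: int = 1, factor: float = 3.0,
                        culture: str = "C1", drug_a: str = "A",
                        drug_b: str = "B") -> DoseMatrix:
    """Noise-free DoseMatrix whose edges follow the two Hill curves.

    ``combo_fn(va, vb, da, db)`` gives the combination-well viability;
    default is the Bliss product.
    """
    if combo_fn is None:
        combo_fn = lambda va, vb, da, db: va * vb
    doses_a = top_a / factor ** np.arange(n)
    doses_b = top_b / factor ** np.arange(n)
    ax_a = np.concatenate([[0.0], np.sort(doses_a)])
    ax_b = np.concatenate([[0.0], np.sort(doses_b)])
    grid = np.empty((n_replicates, n + 1, n + 1))
    for i, da in enumerate(ax_a):
        for j, db in enumerate(ax_b):
            va, vb = fit_a.predict(da), fit_b.predict(db)
            if i == 0 and j == 0:
                v = 0.5 * (fit_a.e0 + fit_b.e0)
            elif j == 0:
                v = va
            elif i == 0:
                v = vb
            else:
                v = combo_fn(va, vb, da, db)
            grid[:, i, j] = v
    return DoseMatrix(culture=culture, drug_a=drug_a, drug_b=drug_b,
                      doses_a=doses_a, doses_b=doses_b, viability=grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
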