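import numpy as np
import pandas as pd
import pytest

from revsig.meta_signature import DiseaseSignature, ExpressionStudy
from revsig.signature_scoring import DrugProfile


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """Six genes, 3 tumor + 3 normal samples, no probe structure."""
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(6)]
    samples = ["T0", "T1", "T2", "N0", "N1", "N2"]
    m = pd.DataFrame(rng.normal(7, 1, (6, 6)), index=genes, columns=samples)
    labels = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=samples)
    return ExpressionStudy(matrix=m, labels=labels, platform_id="GPLT")


@pytest.fixture
def small_signature() -> DiseaseSignature:
    up = pd.DataFrame({"combined_log2fc": [2.0, 1.8], "q": [1e-5, 1e-4]},
                      index=["g1", "g2"])
    down = pd.DataFrame({"combined_log2fc": [-2.2, -1.9], "q": [1e-5, 1e-4]},
                        index=["g3", "g4"])
    return DiseaseSignature(up=up, down=down)


def make_profile(values: dict[str, float], profile_id: str = "p1",
                 compound: str = "c1", cell_line: str = "PC3",
                 dose: float = 10.0, duration: float = 24.0,
                 gold: bool = True) -> DrugProfile:
    return DrugProfile(profile_id=profile_id, compound=compound,
                       cell_line=cell_line, dose_um=dose,
                       duration_h=duration, is_gold=gold,
                       values=pd.Series(values))
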