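import numpy as np
import pandas as pd
import pytest

from ccmeta.observations import SCHEMA_COLUMNS


def make_obs_csv(path, rows):
    """Write a schema-conforming observation CSV from partial row dicts."""
    full = []
    for r in rows:
        base = {c: "" for c in SCHEMA_COLUMNS}
        base.update({k: str(v) for k, v in r.items()})
        full.append(base)
    pd.DataFrame(full, columns=list(SCHEMA_COLUMNS)).to_csv(path, index=False)
    return path


@pytest.fixture
def obs_csv_factory(tmp_path):
    counter = iter(range(10**6))

    def factory(rows, name=None):
        name = name or f"obs{next(counter)}.csv"
        return make_obs_csv(tmp_path / name, rows)

    return factory


@pytest.fixture
def leaching_rows():
    """Six hand-built leaching comparisons across 3 articles, 2 families."""
    return [
        {"article_id": "a1", "obs_id": "o1", "response": "nitrate_leaching",
         "mean_cc": 10, "mean_ncc": 20, "n_cc": 4, "n_ncc": 4,
         "cc_family": "Poaceae", "tillage": "CT", "rainfall_mm": 800, "temp_c": 10},
        {"article_id": "a1", "obs_id": "o2", "response": "nitrate_leaching",
         "mean_cc": 5, "mean_ncc": 20, "n_cc": 3, "n_ncc": 4,
         "cc_family": "Brassicaceae", "tillage": "NT", "rainfall_mm": 900, "temp_c": 12},
        {"article_id": "a2", "obs_id": "o3", "response": "nitrate_leaching",
         "mean_cc": 12, "mean_ncc": 18, "cc_family": "Poaceae",
         "tillage": "CT", "rainfall_mm": 600},
        {"article_id": "a2", "obs_id": "o4", "response": "nitrate_leaching",
         "mean_cc": 8, "mean_ncc": 30, "n_cc": 2, "n_ncc": 2,
         "cc_family": "Brassicaceae", "rainfall_mm": 1100, "temp_c": 8},
        {"article_id": "a3", "obs_id": "o5", "response": "nitrate_leaching",
         "mean_cc": 15, "mean_ncc": 15, "n_cc": 1, "n_ncc": 1,
         "cc_family": "Poaceae", "tillage": "RT", "temp_c": 15},
        {"article_id": "a3", "obs_id": "o6", "response": "nitrate_leaching",
         "mean_cc": 6, "mean_ncc": 22, "n_cc": 4, "n_ncc": 3,
         "cc_family": "Brassicaceae", "rainfall_mm": 700, "temp_c": 9},
    ]


@pytest.fixture
def effects_frame():
    """Minimal effects frame builder for the statistics modules."""

    def build(es, v, **extra):
        es = np.asarray(es, float)
        df = pd.DataFrame({
            "obs_id": [f"o{i}" for i in range(es.size)],
            "article_id": [f"a{i}" for i in range(es.size)],
            "es": es,
            "v": np.asarray(v, float),
        })
        df["w_fixed"] = 1.0 / df["v"]
        for k, vals in extra.items():
            df[k] = vals
        return df

    return build
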