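"""File formats: judgement files, prior/config blocks, result serialisation.

Judgement files are plain delimited text:

* roulette — one row per bin with columns ``lower, upper, chips``;
* quartiles — a single row with columns ``q25, q50, q75``.

Configs are flat YAML mappings; priors serialise to
``{family, params, [lower], [upper]}`` blocks (``{family: point, value: x}``
also accepted), so an elicitation session's output can be pasted straight
into an assurance config.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .design import AssuranceResult, TrialDesign
from .priors import PriorSpec, QuartileJudgement, RouletteJudgement

__all__ = [
    "read_roulette_judgement",
    "read_quartile_judgement",
    "prior_from_config",
    "design_from_config",
    "load_config",
    "write_result",
]


def read_roulette_judgement(path) -> RouletteJudgement:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 3:
        raise ValueError("roulette file needs columns: lower, upper, chips")
    lows = df.iloc[:, 0].to_numpy(dtype=float)
    highs = df.iloc[:, 1].to_numpy(dtype=float)
    chips = df.iloc[:, 2].to_numpy()
    if not np.allclose(lows[1:], highs[:-1]):
        raise ValueError("roulette bins must be contiguous")
    edges = np.concatenate([lows, [highs[-1]]])
    return RouletteJudgement(edges, chips)


def read_quartile_judgement(path) -> QuartileJudgement:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 3 or len(df) < 1:
        raise ValueError("quartile file needs one row with columns: q25, q50, q75")
    row = df.iloc[0]
    return QuartileJudgement(float(row.iloc[0]), float(row.iloc[1]), float(row.iloc[2]))


def prior_from_config(block: dict) -> PriorSpec:
    if "family" not in block:
        raise ValueError("prior block needs a 'family' key")
    family = block["family"]
    if family == "point":
        params = (block["value"],) if "value" in block else tuple(block["params"])
    else:
        params = tuple(block["params"])
    return PriorSpec(family, params, block.get("lower"), block.get("upper"))


def design_from_config(block: dict) -> TrialDesign:
    try:
        if "n_total" in block:
            return TrialDesign.from_total(
                block["R"], block["T"], block["n_total"],
                block.get("q1", 0.5), block.get("q2", 0.5), block.get("alpha", 0.05),
            )
        return TrialDesign(
            block["R"], block["T"], block["n1"], block["n2"], block.get("alpha", 0.05)
        )
    except KeyError as exc:
        raise ValueError(f"design block is missing required field {exc}") from exc


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_result(result: AssuranceResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
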