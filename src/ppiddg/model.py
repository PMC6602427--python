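"""Regressor training, prediction, persistence and interface scanning.

The learner is an extremely-randomised-trees ensemble over the named
feature vector; the prediction target is ddG = dG_wild-type -
dG_mutant in kcal/mol. Scanning modes enumerate interface residues (the
5 A heavy-atom rule) and predict either the alanine substitution at
each non-alanine position or all 19 substitutions per position.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from ppiddg import data as tables
from ppiddg import interactions as ia
from ppiddg.pipeline import FeatureConfig, FeaturePipeline
from ppiddg.structure_io import ResidueRef, Structure

PERSISTENCE_VERSION = 1

DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 500,
    "max_depth": None,
    "min_samples_leaf": 1,
    "max_features": 1.0,
}


class SchemaMismatchError(ValueError):
    """Prediction input slots differ from the training schema."""


@dataclass
class TrainedModel:
    learner: ExtraTreesRegressor
    schema: tuple[str, ...]
    seed: int
    hyperparameters: dict
    training_fingerprint: str
    version: int = PERSISTENCE_VERSION

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        obj = joblib.load(path)
        if not isinstance(obj, TrainedModel):
            raise ValueError(f"{path} is not a ppiddg model file")
        if obj.version != PERSISTENCE_VERSION:
            raise ValueError(f"model file version {obj.version} not supported")
        return obj


def _fingerprint(features: pd.DataFrame, targets: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(",".join(features.columns).encode())
    h.update(np.ascontiguousarray(features.to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(targets, float)).tobytes())
    return h.hexdigest()[:16]


def train(features: pd.DataFrame, targets, config: dict | None = None,
          seed: int = 0) -> TrainedModel:
    """Fit the tree ensemble on a named feature table.

    Deterministic for a given seed; refuses NaN targets and undersized
    tables (fewer than 10 rows).
    """
    targets = np.asarray(targets, dtype=float)
    if len(features) != len(targets):
        raise ValueError("features and targets differ in length")
    if len(features) < 10:
        raise ValueError("need at least 10 training rows")
    if not np.isfinite(targets).all():
        raise ValueError("targets contain non-finite values")
    params = {**DEFAULT_HYPERPARAMETERS, **(config or {})}
    learner = ExtraTreesRegressor(random_state=seed, **params)
    learner.fit(features.to_numpy(float), targets)
    return TrainedModel(
        learner=learner,
        schema=tuple(features.columns),
        seed=seed,
        hyperparameters=params,
        training_fingerprint=_fingerprint(features, targets),
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted ddG (kcal/mol, wt - mt convention), one value per row."""
    schema = tuple(features.columns)
    if schema != model.schema:
        for got, want in zip(schema, model.schema):
            if got != want:
                raise SchemaMismatchError(
                    f"feature slot mismatch: got '{got}', model expects "
                    f"'{want}'")
        raise SchemaMismatchError(
            f"feature count mismatch: got {len(schema)} slots, model "
            f"expects {len(model.schema)}")
    return model.learner.predict(features.to_numpy(float))


# ---------------------------------------------------------------------------
# synthetic training data (parameter-recovery harness)


def make_synthetic_features(n: int, n_features: int = 30, seed: int = 0,
                            noise_sd: float = 0.1
                            ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table with a planted linear target on the first 5 slots.

    y = 2 x0 - 1.5 x1 + x2 + 0.5 x3 - x4 + N(0, noise_sd); slots are
    standard normal. Used to verify the learner recovers a known signal.
    """
    if n_features < 5:
        raise ValueError("need at least 5 feature slots for the planted signal")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n_features))
    coef = np.zeros(n_features)
    coef[:5] = [2.0, -1.5, 1.0, 0.5, -1.0]
    y = x @ coef + rng.normal(scale=noise_sd, size=n)
    cols = [f"x{i}" for i in range(n_features)]
    return pd.DataFrame(x, columns=cols), y


# ---------------------------------------------------------------------------
# scanning modes


@dataclass
class ScanResult:
    """Predictions for an interface scan."""

    rows: pd.DataFrame             # chain, res_number, icode, wt_aa, mut_aa, ddg_pred
    interface_id: tuple[str, str]
    per_residue_mean: pd.DataFrame  # chain, res_number, icode, wt_aa, mean_ddg_pred

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")


def _interface_refs(s: Structure, interface_cutoff: float
                    ) -> dict[tuple[str, str], list[ResidueRef]]:
    interfaces = ia.interface_residues(s, interface_cutoff)
    out = {}
    for pair, members in sorted(interfaces.items()):
        refs = []
        for chain_id, num, icode in sorted(members):
            refs.append(ResidueRef(chain_id, num, icode))
        out[pair] = refs
    return out


def _scan(model: TrainedModel, s: Structure, mutants_for,
          config: FeatureConfig | None, interface: tuple[str, str] | None
          ) -> list[ScanResult]:
    config = config or FeatureConfig()
    all_ifaces = _interface_refs(s, config.interface_cutoff)
    if not all_ifaces:
        raise ValueError("no interface found within cutoff")
    if interface is not None:
        all_ifaces = {interface: all_ifaces[interface]}
    results = []
    for pair, refs in all_ifaces.items():
        pipe = FeaturePipeline(s, config)
        rows = []
        for ref in refs:
            wt_aa = s.get_residue(ref).aa
            for mut_aa in mutants_for(wt_aa):
                vec = pipe.feature_vector(ref, mut_aa)
                pred = predict(model, pd.DataFrame(
                    [vec.values], columns=list(vec.names)))[0]
                rows.append({"chain": ref.chain_id, "res_number": ref.res_number,
                             "icode": ref.icode, "wt_aa": wt_aa,
                             "mut_aa": mut_aa, "ddg_pred": float(pred)})
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=["chain", "res_number", "icode",
                                       "wt_aa", "mut_aa", "ddg_pred"])
        means = (df.groupby(["chain", "res_number", "icode", "wt_aa"],
                            as_index=False)["ddg_pred"].mean()
                 .rename(columns={"ddg_pred": "mean_ddg_pred"})
                 if not df.empty else
                 pd.DataFrame(columns=["chain", "res_number", "icode",
                                       "wt_aa", "mean_ddg_pred"]))
        results.append(ScanResult(rows=df, interface_id=pair,
                                  per_residue_mean=means))
    return results


def alanine_scan(model: TrainedModel, s: Structure,
                 config: FeatureConfig | None = None,
                 interface: tuple[str, str] | None = None) -> list[ScanResult]:
    """Mutate every non-alanine interface residue to alanine."""
    return _scan(model, s,
                 lambda wt: [] if wt == "A" else ["A"],
                 config, interface)


def saturation_scan(model: TrainedModel, s: Structure,
                    config: FeatureConfig | None = None,
                    interface: tuple[str, str] | None = None
                    ) -> list[ScanResult]:
    """Mutate every interface residue to each of the 19 other amino acids."""
    return _scan(model, s,
                 lambda wt: [aa for aa in tables.ALPHABET if aa != wt],
                 config, interface)
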