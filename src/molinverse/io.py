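"""File exchange: XYZ geometries, dataset archives, model checkpoints, YAML."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .molecule import SYMBOL_TO_Z, Z_TO_SYMBOL, Molecule


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, mol: Molecule, comment=""):
    """Write one molecule in XYZ format (element symbols, angstrom)."""
    lines = [str(mol.n_atoms), str(comment).replace("\n", " ")]
    for z, (x, y, zc) in zip(mol.species, mol.coords):
        lines.append(f"{Z_TO_SYMBOL[z]} {x:.10f} {y:.10f} {zc:.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> Molecule:
    """Read the first frame of an XYZ file."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    n = int(lines[0])
    species, coords = [], []
    for ln in lines[2 : 2 + n]:
        sym, x, y, z = ln.split()[:4]
        species.append(SYMBOL_TO_Z[sym])
        coords.append([float(x), float(y), float(z)])
    return Molecule(tuple(species), np.array(coords))


# ---------------------------------------------------------------------------
# dataset archives (binary array archive; cache format, not a deliverable)
# ---------------------------------------------------------------------------

def save_dataset(path, dataset):
    """Persist a SyntheticDataset to a .npz archive."""
    coords = np.concatenate([m.coords for m in dataset.molecules])
    sizes = np.array([m.n_atoms for m in dataset.molecules])
    species = np.concatenate([np.array(m.species) for m in dataset.molecules])
    np.savez_compressed(
        path,
        X=dataset.X,
        Y=dataset.Y.values,
        property_names=np.array(dataset.Y.columns, dtype=str),
        split=dataset.split.astype(str),
        coords=coords,
        sizes=sizes,
        species=species,
        layout=np.array(dataset.layout.slots),
        spec=np.array(json.dumps(_spec_dict(dataset.spec)), dtype=str),
    )


def load_dataset(path):
    from .coulomb import CoulombLayout
    from .synthetic import SyntheticDataset, SyntheticDatasetSpec

    with np.load(path, allow_pickle=False) as arc:
        offsets = np.concatenate([[0], np.cumsum(arc["sizes"])])
        molecules = [
            Molecule(
                tuple(arc["species"][a:b].tolist()),
                arc["coords"][a:b],
            )
            for a, b in zip(offsets[:-1], offsets[1:])
        ]
        layout = CoulombLayout(tuple(map(tuple, arc["layout"])))
        spec_kwargs = json.loads(str(arc["spec"]))
        spec = SyntheticDatasetSpec(**spec_kwargs)
        Y = pd.DataFrame(arc["Y"], columns=list(arc["property_names"]))
        return SyntheticDataset(spec, molecules, layout, arc["X"], Y, arc["split"])


def _spec_dict(spec):
    return {
        "n": spec.n,
        "elements": list(spec.elements),
        "max_atoms": spec.max_atoms,
        "bond_range": list(spec.bond_range),
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_model(path, model):
    """Single-file checkpoint: hyperparameters + statistics + all weights."""
    arrays = {
        "cm_scale": np.array(model.cm_scale_),
        "prop_mean": model.prop_mean_,
        "prop_scale": model.prop_scale_,
        "config": np.array(json.dumps(model.get_params()), dtype=str),
    }
    for name, net in (
        ("encoder", model.encoder_),
        ("decoder", model.decoder_),
        ("property_encoder", model.property_encoder_),
    ):
        arrays[f"{name}_sizes"] = np.array(net.sizes)
        for i, (w, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"{name}_w{i}"] = w
            arrays[f"{name}_b{i}"] = b
    np.savez_compressed(path, **arrays)


def load_model(path):
    from .model import PropertyStructureVAE
    from .nn import MLP

    with np.load(path, allow_pickle=False) as arc:
        params = json.loads(str(arc["config"]))
        for key in ("encoder_hidden", "property_hidden"):
            params[key] = tuple(params[key])
        model = PropertyStructureVAE(**params)
        model.cm_scale_ = float(arc["cm_scale"])
        model.prop_mean_ = arc["prop_mean"]
        model.prop_scale_ = arc["prop_scale"]
        rng = np.random.default_rng(0)
        for name in ("encoder", "decoder", "property_encoder"):
            sizes = arc[f"{name}_sizes"].tolist()
            net = MLP(sizes, rng)
            n_layers = len(sizes) - 1
            net.weights = [arc[f"{name}_w{i}"] for i in range(n_layers)]
            net.biases = [arc[f"{name}_b{i}"] for i in range(n_layers)]
            setattr(model, f"{name}_", net)
        model.n_features_in_ = model.encoder_.sizes[0]
        model.n_properties_in_ = model.property_encoder_.sizes[0]
    return model


def save_mixture(path, mixture):
    """Single-file archive of a fitted property mixture (raw-unit parameters)."""
    np.savez_compressed(
        path,
        weights=mixture.weights_,
        means=mixture.means_,
        covariances=mixture.covariances_,
        k=np.array(mixture.k_),
        bic_k=np.array(sorted(mixture.bic_)),
        bic_values=np.array([mixture.bic_[k] for k in sorted(mixture.bic_)]),
        config=np.array(json.dumps(mixture.get_params()), dtype=str),
    )


def load_mixture(path):
    from .propspace import PropertyMixtureModel

    with np.load(path, allow_pickle=False) as arc:
        params = json.loads(str(arc["config"]))
        params["k_grid"] = tuple(params["k_grid"])
        mixture = PropertyMixtureModel(**params)
        mixture.weights_ = arc["weights"]
        mixture.means_ = arc["means"]
        mixture.covariances_ = arc["covariances"]
        mixture.k_ = int(arc["k"])
        mixture.bic_ = dict(zip(arc["bic_k"].tolist(), arc["bic_values"].tolist()))
    return mixture


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg
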