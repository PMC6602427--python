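"""End-to-end feature computation for one mutation on one complex.

Glue between the structural modules and the learner: given a structure
and a mutation, compute every feature block and assemble the vector.
Wild-type-only blocks (signature, environment, network, fluctuations)
are cached per residue so scanning modes do not recompute them for each
of the 19 candidate substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ppiddg import features as ft
from ppiddg import interactions as ia
from ppiddg import signatures as sg
from ppiddg import structure_io as sio
from ppiddg.structure_io import ResidueRef, Structure


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature pipeline."""

    environment_radius: float = sg.DEFAULT_RADIUS
    cutoffs: tuple[float, ...] = sg.DEFAULT_CUTOFFS
    interface_cutoff: float = ia.INTERFACE_CUTOFF
    include_potentials: bool = True
    include_fluctuation: bool = True
    potentials: list | None = None          # parsed AAindex tables

    def resolved_potentials(self):
        if self.potentials is None:
            self.potentials = ft.default_contact_potentials()
        return self.potentials


@dataclass
class _SiteCache:
    signature: object = None
    environment: dict | None = None
    network: object = None
    wt_contacts: object = None
    fluctuation: dict | None = None


class FeaturePipeline:
    """Computes feature vectors for mutations of one structure."""

    def __init__(self, structure: Structure,
                 config: FeatureConfig | None = None):
        self.structure = structure
        self.config = config or FeatureConfig()
        self._contacts = None
        self._site_cache: dict[tuple, _SiteCache] = {}
        self._fluct_cache: dict[str, dict[str, list[float]]] = {}

    # -- wild-type blocks ----------------------------------------------
    def _contacts_all(self):
        if self._contacts is None:
            self._contacts = ia.detect_contacts(self.structure)
        return self._contacts

    def _chain_fluctuations(self, chain_id: str):
        if chain_id not in self._fluct_cache:
            mono = ft.monomer_view(self.structure, chain_id)
            self._fluct_cache[chain_id] = {
                ff: ft.enm_fluctuations(mono, ff).fluctuations
                for ff in ("calpha", "pfanm")
            }
        return self._fluct_cache[chain_id]

    def _site(self, ref: ResidueRef) -> _SiteCache:
        key = (ref.chain_id, ref.res_number, ref.icode or "")
        if key in self._site_cache:
            return self._site_cache[key]
        s, cfg = self.structure, self.config
        cache = _SiteCache()
        env = sg.extract_environment(s, ref, cfg.environment_radius)
        cache.signature = sg.cutoff_scan_signature(env, cfg.cutoffs)
        chain = s.chain(ref.chain_id)
        cache.environment = {
            "rsa": sio.relative_solvent_accessibility(s, ref),
            "phi": sio.phi_torsion(s, ref),
            "depth": sio.residue_depth(s, ref),
            "aa_composition": sio.aa_composition(chain.sequence()),
        }
        interface = ia.closest_interface(s, ref, cfg.interface_cutoff)
        net = ia.build_contact_network(s, interface, cfg.interface_cutoff,
                                       contacts=self._contacts_all())
        cache.network = ia.network_metrics(net)
        cache.wt_contacts = ia.residue_contact_counts(self._contacts_all(), key)
        if cfg.include_fluctuation:
            profs = self._chain_fluctuations(ref.chain_id)
            res = s.get_residue(ref)
            idx = chain.residues.index(res)
            cache.fluctuation = {
                "calpha_site": float(profs["calpha"][idx]),
                "calpha_mean": float(profs["calpha"].mean()),
                "pfanm_site": float(profs["pfanm"][idx]),
                "pfanm_mean": float(profs["pfanm"].mean()),
            }
        self._site_cache[key] = cache
        return cache

    # -- per-mutation vector -------------------------------------------
    def feature_vector(self, ref: ResidueRef, mut_aa: str,
                       pssm: ft.PSSM | None = None,
                       energy: ft.EnergyTerms | None = None) -> ft.FeatureVector:
        s, cfg = self.structure, self.config
        res = s.get_residue(ref)
        wt_aa = res.aa
        cache = self._site(ref)

        key = (ref.chain_id, ref.res_number, ref.icode or "")
        mut = ia.mutate_residue(s, ref, mut_aa)
        mut_counts = ia.residue_contact_counts(ia.detect_contacts(mut), key)
        delta = ia.ContactDelta(*(cache.wt_contacts[k] - mut_counts[k]
                                  for k in ia.CONTACT_KINDS))

        evolution = None
        if pssm is not None:
            chain = s.chain(ref.chain_id)
            pos = chain.residues.index(res) + 1
            evolution = ft.evolutionary_scores(pssm, pos, wt_aa, mut_aa)

        potentials = None
        if cfg.include_potentials:
            potentials = ft.contact_potential_scores(
                wt_aa, mut_aa, cfg.resolved_potentials())

        return ft.assemble_features(
            signature=cache.signature,
            environment=cache.environment,
            flags=ft.gly_pro_flags(wt_aa, mut_aa),
            contact_delta=delta,
            network=cache.network,
            evolution=evolution,
            potentials=potentials,
            fluctuation=cache.fluctuation,
            energy=energy,
        )


def features_for_mutations(structure: Structure,
                           mutations: list[tuple[ResidueRef, str]],
                           config: FeatureConfig | None = None,
                           pssm: ft.PSSM | None = None) -> pd.DataFrame:
    """Feature table (one row per mutation) for a batch of mutations."""
    pipe = FeaturePipeline(structure, config)
    vectors = [pipe.feature_vector(ref, mut, pssm=pssm)
               for ref, mut in mutations]
    return ft.feature_frame(vectors)
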