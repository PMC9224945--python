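"""Deterministic synthetic containers for tests and demos.

Every input the package needs can be generated here: random block
payloads, archive-style study metadata and policy templates (all-permit,
all-deny, or the worked-example privacy rule), all driven by a single
seed so the same specification always yields byte-identical packed
containers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from genovault import container as cont
from genovault import metadata as md
from genovault import policy as pol
from genovault import protection as prot

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "generate_random_container",
    "policy_from_template",
    "TEMPLATES",
]

TEMPLATES = ("all-permit", "all-deny", "worked-example")


def policy_from_template(name: str) -> pol.Policy:
    if name == "all-permit":
        return pol.Policy(
            "all-permit", (pol.PolicyRule("permit-everything", pol.Effect.PERMIT),)
        )
    if name == "all-deny":
        return pol.Policy(
            "all-deny", (pol.PolicyRule("deny-everything", pol.Effect.DENY),)
        )
    if name == "worked-example":
        return pol.build_worked_example()[0]
    raise ValueError(f"unknown policy template {name!r} (choose from {TEMPLATES})")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_groups: int = 2
    n_datasets: int = 2
    n_access_units: int = 1
    n_blocks: int = 1
    block_size: int = 256
    policy_template: Optional[str] = "all-permit"  # None -> no policies


def generate_fixture(
    spec: FixtureSpec, root_path: Union[str, Path]
) -> cont.GenomicContainer:
    """Build a populated container: random blocks, EGA-style metadata and
    the selected policy template at both group and dataset level."""
    if min(spec.n_groups, spec.n_datasets, spec.n_access_units, spec.n_blocks) < 0 or (
        spec.block_size < 0
    ):
        raise ValueError("fixture dimensions must be non-negative")
    rng = random.Random(spec.seed)
    c = cont.create_container(root_path, brand="genovault-fixture")
    for dg_id in range(spec.n_groups):
        cont.add_dataset_group(c, dg_id)
        record = md.map_from_ega(
            {
                "Study-STUDY_TITLE": f"Synthetic study {dg_id}",
                "Study-STUDY_TYPE": "Whole Genome Sequencing",
                "Study-STUDY_ABSTRACT": f"Seeded synthetic fixture group {dg_id}.",
                "Study-CENTER_PROJECT_NAME": "genovault",
                "Study-STUDY_DESCRIPTION": f"Randomly generated payload, seed {spec.seed}.",
                "Assembly-TAXON_ID": "9606",
                "Assembly-TITLE": "GRCh38",
            }
        )
        cont.attach_metadata(c, f"dg_{dg_id}", record)
        if spec.policy_template is not None:
            cont.attach_protection(
                c,
                f"dg_{dg_id}",
                prot.ProtectionBox(policy=policy_from_template(spec.policy_template)),
            )
        for dt_id in range(spec.n_datasets):
            cont.add_dataset(c, dg_id, dt_id)
            sample = md.MetadataRecord(
                title=f"Sample {dg_id}.{dt_id}",
                sample_taxon_id="9606",
                sample_title=f"synthetic-sample-{dg_id}-{dt_id}",
            )
            md.add_extension(sample, "IsTumor", rng.choice(["yes", "no"]))
            cont.attach_metadata(c, f"dg_{dg_id}/dt_{dt_id}", sample)
            if spec.policy_template is not None:
                cont.attach_protection(
                    c,
                    f"dg_{dg_id}/dt_{dt_id}",
                    prot.ProtectionBox(
                        policy=policy_from_template(spec.policy_template)
                    ),
                )
            for au_id in range(spec.n_access_units):
                cont.add_access_unit(c, dg_id, dt_id, au_id)
                for _ in range(spec.n_blocks):
                    cont.add_block(
                        c, dg_id, dt_id, au_id, rng.randbytes(spec.block_size)
                    )
    return c


def generate_random_container(
    seed: int,
    root_path: Union[str, Path],
    max_groups: int = 3,
    max_datasets: int = 3,
    max_access_units: int = 3,
    max_blocks: int = 4,
    max_block_size: int = 65536,
) -> cont.GenomicContainer:
    """Random-shape container for round-trip property testing.

    Tree dimensions, block sizes, optional labels, metadata, info payloads,
    indices and policy boxes are all drawn from one seeded stream, so the
    same seed always reproduces the same container.  Block sizes are skewed
    small with occasional blocks at ``max_block_size``.
    """
    rng = random.Random(seed)
    c = cont.create_container(root_path, brand=f"random-{seed}")
    for dg_id in range(rng.randint(0, max_groups)):
        cont.add_dataset_group(c, dg_id, note=f"g{rng.randint(0, 999)}")
        if rng.random() < 0.5:
            cont.attach_metadata(
                c,
                f"dg_{dg_id}",
                md.MetadataRecord(title=f"study-{rng.randint(0, 999)}"),
            )
        if rng.random() < 0.4:
            cont.attach_protection(
                c,
                f"dg_{dg_id}",
                prot.ProtectionBox(policy=policy_from_template(rng.choice(TEMPLATES))),
            )
        for dt_id in range(rng.randint(0, max_datasets)):
            dt = cont.add_dataset(c, dg_id, dt_id)
            if rng.random() < 0.5:
                dt.label = f"label-{rng.randint(0, 999)}"
                (c.dataset_dir(dg_id, dt_id) / "labl").write_bytes(
                    dt.label.encode()
                )
            if rng.random() < 0.3:
                cont.attach_metadata(
                    c,
                    f"dg_{dg_id}/dt_{dt_id}",
                    md.MetadataRecord(sample_title=f"s-{rng.randint(0, 999)}"),
                )
            n_aus = rng.randint(0, max_access_units)
            for au_id in range(n_aus):
                au = cont.add_access_unit(c, dg_id, dt_id, au_id)
                if rng.random() < 0.3:
                    au.info = rng.randbytes(rng.randint(1, 32))
                    (c.au_dir(dg_id, dt_id, au_id) / "auin").write_bytes(au.info)
                for _ in range(rng.randint(0, max_blocks)):
                    size = (
                        max_block_size
                        if rng.random() < 0.05
                        else rng.randint(0, 2048)
                    )
                    cont.add_block(c, dg_id, dt_id, au_id, rng.randbytes(size))
            if n_aus and rng.random() < 0.3:
                dt.index = {au_id: rng.randint(0, 10**6) for au_id in range(n_aus)}
                import json as _json

                (c.dataset_dir(dg_id, dt_id) / "dtix").write_bytes(
                    _json.dumps(
                        {"au_offsets": {str(k): v for k, v in dt.index.items()}}
                    ).encode()
                )
    return c
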