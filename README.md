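# genovault

Protected hierarchical genomic containers: selective encryption, privacy
rules, hierarchical authorization, and encrypted envelopes with range
access.

## The problem

Genomic data is uniquely sensitive — a leak exposes not just one person but
their relatives, permanently — yet the formats it usually lives in (FASTQ,
SAM/BAM, CRAM) carry no protection of their own. `genovault` implements the
computational core of a standards-style protection stack for genomic
archives, aimed at data stewards and infrastructure developers:

* a **hierarchical container** (File → Dataset Groups → Datasets → Access
  Units → Blocks) in which every level can carry metadata and a
  *protection box*; a Dataset Group corresponds to an EGA Study / NCBI
  BioProject, a Dataset to an EGA dataset / NCBI BioSample;
* **selective protection**: any single block or metadata file can be
  encrypted (ChaCha20-Poly1305) or signed (Ed25519) independently, with
  entries, wrapped keys and policies recorded in the enclosing level's
  protection box;
* **privacy rules** in an XACML 3.0 subset: attribute-based rules over the
  subject role, the API action, and genomic conditions (situation, read
  count, multiple alignments, reference sequence and position interval),
  combined with deny-overrides / permit-overrides / first-applicable;
* **hierarchical authorization**: a dataset request is decided by the
  dataset's own rules first (a dataset Permit is never overridden by the
  group), falling back to the group's rules with an explicit
  `granted_by_dataset_group` provenance attribute; a group-wide request is
  reviewed dataset by dataset so that a dataset with different rules is
  blocked while the rest is returned;
* a **Crypt4GH-style encrypted envelope**: per-reader header packets found
  by trial decryption, independently authenticated 64 KiB data segments,
  and range decryption that touches only the segments overlapping the
  requested byte interval.

Everything is a library first (`genovault.container`, `.policy`,
`.hierarchy_authz`, `.protection`, `.crypt4gh`, `.metadata`, `.search`,
`.fixtures`) with a thin `genovault` CLI on top.

## Worked example

The packaged reference rule permits `GetDataBySimpleFilter` for the role
`practitioner` only under an emergency, for at most 5000 reads, without
multiple alignments, on reference sequence 4 within positions
40,810,027–41,216,714 (both ends included) — a rule protecting a region
associated with Alzheimer's-disease predisposition. Build a container,
attach the rule at the dataset level, and ask for decisions:

```
$ genovault create box --owner alice
created container at box
$ genovault add-dg box 0 --subject-id alice
added dg_0
$ genovault add-dt box 0 0 --subject-id alice
added dg_0/dt_0
$ genovault attach-policy box dg_0/dt_0 --template worked-example --subject-id alice
policy 'alzheimer-region-policy' attached at dg_0/dt_0

$ genovault authorize box --op GetDataBySimpleFilter --target dg_0/dt_0 \
    --role researcher --date 2022-05-31
decision: Deny        # exit status 3: the role does not match the rule

$ genovault authorize box --op GetDataBySimpleFilter --target dg_0/dt_0 \
    --role practitioner --situation Emergency \
    --attr read_count=int:5000 --attr presence_of_multiple_alignments=bool:false \
    --attr reference_id=int:4 \
    --attr start_position=int:40810027 --attr end_position=int:41216714
decision: Permit (granted by dataset)
```

The first request is refused because the subject's role differs from the
one in the rule; the second satisfies the target and every condition, and
is granted by the dataset's own policy. `genovault pack box box.gv` then
serialises the directory layout into a single deterministic container
file, and `genovault c4gh encrypt` wraps any file in the encrypted
envelope for a set of reader keys.

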