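# genestruct

Bidirectional coordinate mapping across three coordinate systems — genome,
protein sequence (splice isoforms and a canonical reference), and
3D-structure residue numbering — plus provenance-tagged annotation tracks on
the canonical sequence with JSON and BED export.

A genomic position is pushed through four stages (and back):

1. **codon arithmetic** — transcript CDS geometry (strand, exon junctions,
   phase) maps a genomic base to a residue of that transcript's translation;
2. **isoform selection** — the translation is matched to the protein isoform
   it actually encodes (exact match, or best global alignment above a
   configurable identity threshold);
3. **canonical projection** — a block alignment projects isoform positions
   onto the canonical sequence of the accession;
4. **structure lookup** — a residue-level mapping table (TSV dialect keyed by
   pdb/chain/accession, with author numbering, insertion codes and observed
   flags) connects canonical positions to structure residues.

## Layout

| module | role |
| --- | --- |
| `genestruct.genome_model` | FASTA/GFF3 I/O, coordinate conventions, transcript validation |
| `genestruct.codon_mapper` | genomic ↔ protein position arithmetic, translation |
| `genestruct.isoform_mapper` | isoform FASTA I/O, affine-gap block aligner, position projection |
| `genestruct.structure_mapper` | residue-mapping TSV I/O, canonical ↔ structure lookup, composed pipeline |
| `genestruct.feature_tracks` | exon/variant/coverage/mismatch/user tracks, JSON + BED6 export |
| `genestruct.fixtures` | deterministic synthetic bundles with independent per-base ground truth |
| `genestruct.cli` | `genestruct` command-line entry point |

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive), BED
(0-based half-open) and user-facing point positions (1-based) convert at the
boundary.

## CLI

All commands take resources either as flags or via `--config file` with
`key=value` lines (keys: `genome`, `gff3`, `isoforms`, `mapping`,
`variants`, `features`, `identity_threshold`).

```sh
# write the built-in demo bundle (deterministic; use --seed N for random genes)
genestruct fixtures demo/

ARGS="--genome demo/genome.fa --gff3 demo/genes.gff3 \
      --isoforms demo/isoforms.fa --mapping demo/mapping.tsv"

genestruct map chrT:107 $ARGS          # genome -> structure (JSON)
genestruct rmap 1XYZ A 101 $ARGS       # structure -> genome codons (JSON)
genestruct tracks ACC1 $ARGS \
    --variants demo/variants.tsv --features demo/user_features.tsv
genestruct bed T1 --pdb 1XYZ $ARGS     # structure coverage as BED6
genestruct validate $ARGS              # transcript sanity findings
```

Exit codes: 0 success (including "no mapping", with reasons in the JSON),
2 usage/input error, 1 internal error. Logs go to stderr, machine output to
stdout/files.

The track JSON schema ships at
`src/genestruct/schemas/feature_tracks.schema.json`; documents are validated
with the pydantic models in `genestruct.track_schema`.

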