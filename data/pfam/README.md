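# PFAM validation inputs (not bundled)

Place PFAM release 27.0 **full** alignments here to enable the
paper-number validation tests and the t1–t5 entries of
`scripts/acceptance.py`:

- `PF00071_full.sto` (G proteins; reference id contains `RASH_HUMAN`)
- `PF00186_full.sto` (DHFR; reference id contains `DYR_ECOLI`)
- `PF13354_full.sto` (class A beta-lactamases; reference id contains `BLAT_ECOLI`)

`.stockholm`, `.fasta`, or `.an` (free FASTA) extensions are also
recognized. These files are large and release-specific, and this
environment has no network access, so they are not redistributed with the
package.
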