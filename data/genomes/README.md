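# Deposited genome records

Place the four GenBank flat files of the sequenced consortium strains here
to enable the published-statistics reproduction
(`analysis/07_deposited_genomes.py` and the corresponding acceptance test):

| file          | genome                        |
|---------------|-------------------------------|
| `CP002918.gb` | tiny GC-rich genome, str. PCVAL  |
| `CP002244.gb` | tiny GC-rich genome, str. PCIT   |
| `CP003881.gb` | mid-sized AT-biased genome, str. PCVAL |
| `CP002243.gb` | mid-sized AT-biased genome, str. PCIT  |

Fetch from NCBI nuccore, e.g.

```
efetch -db nuccore -id CP003881 -format gb > CP003881.gb
```

The records are not redistributed with this repository.
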