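# sspcr — genome walking by semi-site-specific primer PCR

`sspcr` is a design and simulation toolkit for a two-round genome-walking
PCR scheme built around a *semi-site-specific primer*: a secondary-round
primer whose 3′-terminal 10 nt are identical to the 3′ end of the outer
site-specific primer used in the primary round, while its 5′ part is
unrelated sequence.  The package is for molecular biologists who want to

* design rule-compliant walking primer sets (three outer site-specific
  primers I–III, one nested inner primer, and one semi-site-specific partner
  per outer primer) from a known sequence region, and
* predict in silico which products the two nested reactions will enrich
  exponentially, which they will suppress, and what band sizes to expect.

## The scheme

Genome walking retrieves unknown DNA flanking a known region.  Here the
primary PCR is driven by a **single** outer site-specific primer (oSSP).
Stringent cycles only let it prime at its perfect site; one low-stringency
(25 °C) cycle lets it partially anneal on the strand synthesised from that
site.  A candidate product is exponentially amplifiable only if extension
from the partial site runs back **through** the perfect site, stamping a
perfect primer-binding site onto the new strand's 3′ end.  The product is
then flanked by the primer and its reverse complement (a terminal inverted
repeat), so short products fold into hairpins and are suppressed.

The secondary PCR pairs a nested inner primer (iSSP) with the
semi-site-specific primer (semi-oSSP).  In its single reduced-stringency
(40 °C) cycle the semi primer hybridises at the outer-primer terminus of
genuine products via its 10-nt overlap (Wallace Tm 20–40 °C); everything it
primes elsewhere lacks a perfect binding site for any primer and stays
single-stranded.  Partial-annealing admission is modelled 3′-anchored and
ungapped: ≥ 2 consecutive 3′-terminal matches, ≥ 8 total matches, ≤ 60 %
mismatches — or a perfect 3′-terminal run of ≥ 10 nt, which licenses the
overlap event itself.

## Worked example

```python
from sspcr import (SyntheticGenomeSpec, generate_walk_fixture,
                   run_primary, run_secondary, band_report)

fx = generate_walk_fixture(SyntheticGenomeSpec(seed=1))   # 12-kb genome,
outer, semi = fx.primer_set.pair("I")                     # sites at 1.5 & 8 kb
primary = run_primary(fx.template, outer, model=fx.model)
secondary = run_secondary(primary.products, fx.primer_set.inner, semi,
                          model=fx.model)
print(band_report([p for p in secondary if p.amplicon_class == "target"]).sketch())
```

prints

```
lane: predicted products (top = largest)
  ============  8433 bp
  ============  1933 bp
```

one clean band per planted partial-annealing site: the 8433-bp product walks
8.0 kb beyond the junction, the 1933-bp one 1.5 kb, and each length equals
(site − inner-primer start) + semi-primer length — here the site at 9500
minus the inner primer at 1094, plus the 27-nt semi primer, gives 8433.  Everything else the
relaxed cycles touched is classed `nontarget-unamplifiable` or, below 200 bp
between inverted repeats, `suppressed-short`.

The same pipeline is scriptable from a shell:

```sh
sspcr fixture --seed 1 --out-dir fx
sspcr simulate --template fx/template.fasta --primers fx/primers.tsv --out-dir sim
sspcr validate --primers fx/primers.tsv
sspcr design --known-region known.fasta --gene mygene --seed 2 --out-dir out
sspcr scan --primers fx/primers.tsv --template fx/template.fasta --out sites.bed
```

The package ships the published gadA/gadR (*Levilactobacillus brevis*) and
hyg (rice) walking primer sets (`sspcr.bundled_primers()`); all 21 primers
pass every validation rule at the default thresholds.

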