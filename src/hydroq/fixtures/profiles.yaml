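# Ingestion exposure profiles.  AT (days) equals ED (years) * EF (days/year).
profiles:
  children:
    ir: 1.0
    ef: 365.0
    ed: 4.0
    bw: 15.0
    at: 1460.0
  adults:
    ir: 2.0
    ef: 365.0
    ed: 40.0
    bw: 70.0
    at: 14600.0
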