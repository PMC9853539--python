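# Published German phase-of-care cost benchmarks used for external validation.
# Kreis et al. (2020): AOK statutory health insurance claims, 2011-2014,
# incremental cost per incident breast-cancer case, adjusted to 2021 EUR.
source,phase,value_eur
kreis2020,initial,21499
kreis2020,intermediate,2620
kreis2020,terminal,34513
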