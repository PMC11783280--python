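# Default annotation rule set for receptor-binding protein (RBP) cataloguing.
#
# Patterns are case-insensitive regular expressions matched against free-text
# gene product annotations. A record whose annotation matches an inclusion
# pattern is an RBP candidate; if it also matches an exclusion pattern it is
# rejected (RBP-adjacent structural parts such as adaptors and chaperones are
# annotated with RBP-like vocabulary but are not receptor-binding proteins).
# Records matching no inclusion pattern but a hypothetical pattern are routed
# to an external RBP detector rather than decided here.
#
# This file is a curated, user-overridable approximation of the RBP annotation
# vocabulary used in the phage literature; edit freely and pass via --rules.
inclusion:
  - 'tail\s*-?fib(er|re)'
  - 'tail\s*-?spike'
  - 'receptor[\s-]*binding(\s+protein)?'
  - 'receptor[\s-]*recogni[sz]ing'
  - '\bspike\s+protein\b'
  - 'host\s+specificity\s+protein'
  - '\bRBP\b'
  - 'adsorption\s+(protein|apparatus)'
exclusion:
  - 'adaptor'
  - 'chaperone'
  - 'assembly'
  - 'hinge'
  - 'connector'
  - 'structural\s+protein'
  - 'sheath'
  - 'baseplate\s+wedge'
  - 'fibritin'
  - 'collar'
hypothetical:
  - 'hypothetical'
  - 'uncharacteri[sz]ed'
  - 'unknown\s+function'
  - '\bputative\s+protein\b'
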