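# Common English words excluded from alias lookup (lower-cased at load).
a
about
above
across
activity
after
again
against
all
also
among
an
analysis
and
any
are
as
associated
at
based
be
because
been
before
between
both
but
by
can
cancer
case
cases
cell
cells
changes
clinical
compared
control
controls
could
cross
data
decreased
development
different
disease
diseases
during
each
effect
effects
et
evidence
experiment
expression
factor
factors
fig
figure
findings
first
for
found
from
function
further
gene
genes
group
groups
growth
had
has
have
here
high
higher
however
human
identified
immune
important
in
increased
indicate
indicated
induced
infection
into
is
it
its
known
levels
light
liver
low
lower
may
measured
mechanism
mechanisms
mice
model
more
most
mouse
new
no
normal
not
novel
observed
of
on
one
only
or
other
our
over
pathway
pathways
patients
play
potential
present
process
protein
proteins
rate
reduced
regulation
related
report
response
results
role
samples
see
show
showed
shown
shows
signaling
significant
significantly
species
specific
studies
study
such
suggest
suggesting
system
talk
target
than
that
the
their
there
these
this
those
three
through
time
tissue
to
total
treatment
two
type
types
under
used
using
via
was
we
well
were
when
where
which
while
with
within
without
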