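the
of
and
to
in
a
is
that
was
for
it
with
as
his
on
be
at
by
had
not
are
but
from
or
have
an
they
which
one
you
were
her
all
she
there
would
their
we
him
been
has
when
who
will
more
no
if
out
so
said
what
up
its
about
into
than
them
can
only
other
new
some
could
time
these
two
may
then
do
first
any
my
now
such
like
our
over
man
me
even
most
made
after
also
did
many
before
must
through
back
years
where
much
your
way
well
down
should
because
each
just
those
people
how
too
little
state
good
very
make
world
still
own
see
men
work
long
get
here
between
both
life
being
under
never
day
same
another
know
while
last
might
us
great
old
year
off
come
since
against
go
came
right
used
take
three
house
mouse
water
given
added
taken
found
obtained
observed
reported
described
shown
stirred
heated
cooled
washed
dried
filtered
removed
treated
prepared
measured
recorded
performed
carried
allowed
mixture
solution
reaction
product
yield
result
results
method
methods
procedure
sample
samples
analysis
temperature
pressure
experiment
experimental
residue
layer
layers
phase
solvent
overnight
hours
minutes
slowly
rapidly
carefully
dropwise
vacuum
reduced
room
crude
pure
white
yellow
colorless
solid
liquid
oil
powder
crystals
compound
compounds
material
materials
afford
afforded
give
gave
gives
giving
followed
further
final
finally
initial
typical
general
obtained
combined
separated
collected
concentrated
evaporated
purified
column
silica
flash
chromatography
extracted
extraction
aqueous
organic
anhydrous
excess
equivalent
portion
portions
resulting
remaining
corresponding
respectively
approximately
according
previously
literature
present
presence
absence
however
therefore
although
whereas
during
within
without
above
below
across
toward
already
almost
often
usually
sometimes
always
together
around
away
became
become
becomes
began
begin
better
between
beyond
brought
called
cannot
certain
change
changes
clear
clearly
close
common
complete
completely
consider
contains
continued
course
table
figure
section
paper
study
studies
data
values
value
case
cases
number
order
point
part
form
forms
formed
field
level
large
small
high
low
higher
lower
based
free
rich
several
single
second
third
total
different
important
possible
particular
available
addition
additional
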