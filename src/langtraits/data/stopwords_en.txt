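a
about
after
all
also
an
and
any
are
as
at
be
because
been
but
by
can
could
did
do
does
for
from
had
has
have
he
her
him
his
how
i
if
in
into
is
it
its
just
me
my
no
not
of
on
or
our
out
she
so
some
than
that
the
their
them
then
there
these
they
this
to
up
was
we
were
what
when
which
who
will
with
would
you
your
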