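# Minimal English stop-word list used when cleaning trigger-word tables.
a
an
and
are
as
at
be
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
if
in
into
is
it
its
may
might
most
no
not
of
on
or
such
that
the
their
then
there
these
this
those
to
was
were
which
while
will
with
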