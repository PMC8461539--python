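contraction,expansion
can't,cannot
cant,cannot
won't,will not
don't,do not
doesn't,does not
didn't,did not
isn't,is not
aren't,are not
wasn't,was not
weren't,were not
hasn't,has not
haven't,have not
hadn't,had not
shouldn't,should not
wouldn't,would not
couldn't,could not
mustn't,must not
ain't,is not
you'll,you will
you're,you are
you've,you have
you'd,you would
i'm,i am
i've,i have
i'll,i will
i'd,i would
it's,it is
that's,that is
there's,there is
here's,here is
what's,what is
who's,who is
she's,she is
he's,he is
let's,let us
we're,we are
we've,we have
we'll,we will
they're,they are
they've,they have
they'll,they will
&,and
w/,with
w/o,without
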